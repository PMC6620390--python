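group,type,category,count,printed_pct
control,AS,spine_head,825,59.1
control,AS,spine_neck,7,0.5
control,AS,aspiny_shaft,278,19.9
control,AS,spiny_shaft,286,20.5
control,SS,spine_head,8,7.1
control,SS,spine_neck,1,0.9
control,SS,aspiny_shaft,43,38.4
control,SS,spiny_shaft,60,53.6
alzheimer,AS,spine_head,579,50.2
alzheimer,AS,spine_neck,8,0.7
alzheimer,AS,aspiny_shaft,323,28.0
alzheimer,AS,spiny_shaft,243,21.1
alzheimer,SS,spine_head,9,8.8
alzheimer,SS,spine_neck,1,1.0
alzheimer,SS,aspiny_shaft,42,41.2
alzheimer,SS,spiny_shaft,50,49.0
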