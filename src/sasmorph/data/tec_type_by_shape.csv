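group,type,category,count,printed_pct
control,AS,macular,2145,83.8
control,AS,perforated,302,11.8
control,AS,horseshoe,98,3.8
control,AS,fragmented,16,0.6
control,SS,macular,106,83.5
control,SS,perforated,5,3.9
control,SS,horseshoe,16,12.6
control,SS,fragmented,0,0.0
alzheimer,AS,macular,1558,81.4
alzheimer,AS,perforated,221,11.5
alzheimer,AS,horseshoe,101,5.3
alzheimer,AS,fragmented,35,1.8
alzheimer,SS,macular,110,92.5
alzheimer,SS,perforated,8,6.7
alzheimer,SS,horseshoe,1,0.8
alzheimer,SS,fragmented,0,0.0
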