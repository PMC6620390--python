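# Small demonstration run: one synthetic stack, full analysis, published
# table reproduction.  Usage:
#   sasmorph run examples/demo_run.yaml --out rundir/ --seed 1
mode: full
seed: 1
n_stacks: 1
scene:
  volume_shape: [320, 320, 80]
  n_dendrites: 6
  synapse_density: 3.0
frame_margin_nm: 300.0
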