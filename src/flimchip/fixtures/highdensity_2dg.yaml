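# high-density 2DG sample: scene regenerated from the seed at run time
seed: 22
scene:
  density_label: high
  condition: 2DG
  seed: 22
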