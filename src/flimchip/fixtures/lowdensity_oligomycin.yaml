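# low-density oligomycin sample: scene regenerated from the seed at run time
seed: 11
scene:
  density_label: low
  condition: oligomycin
  seed: 11
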