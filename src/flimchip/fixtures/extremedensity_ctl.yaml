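# extreme seeding density: develops a distal necrotic core covering ~80%
# of the chamber length
seed: 33
scene:
  density_label: extreme
  condition: CTL
  seed: 33
  necrotic_core_fraction: 0.8
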