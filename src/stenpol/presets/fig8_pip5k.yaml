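# Two-state PIP5K partitioning (combined mode) with actin/myosin loops.
model:
  feedback:
    pip5k_enabled: true
    pip5k_mode: combined
    actin_enabled: true
    myosin_enabled: true
settings:
  duration: 1200.0
sweep:
  a_act: [0.0, 0.2, 0.8]
  a_myo: [0.0, 0.4]
n_replicates: 5
base_seed: 1
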