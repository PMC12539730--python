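# Reduced polarization-statistics grid for model comparison (3x3, 5 reps).
model:
  feedback:
    actin_enabled: true
    myosin_enabled: true
settings:
  duration: 1200.0
sweep:
  a_act: [0.2, 0.6, 1.0]
  a_myo: [0.2, 0.6, 1.0]
n_replicates: 5
base_seed: 1
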