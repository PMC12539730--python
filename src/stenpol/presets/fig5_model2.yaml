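# Model 2: branched-actin positive feedback x tension global inhibition.
model:
  feedback:
    actin_enabled: true
    tension_enabled: true
    tension_mode: hydrolysis
settings:
  duration: 1200.0
sweep:
  a_act: [0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0]
  a_ten: [0.0, 0.4, 0.8, 1.2, 1.6, 2.0, 2.4, 2.8, 3.2, 3.6, 4.0]
n_replicates: 20
base_seed: 1
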