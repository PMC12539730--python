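# Model 1: branched-actin positive feedback x myosin local inhibition.
model:
  feedback:
    actin_enabled: true
    myosin_enabled: true
settings:
  duration: 1200.0
sweep:
  a_act: [0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0]
  a_myo: [0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0]
n_replicates: 20
base_seed: 1
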