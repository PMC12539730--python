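# PIP5K level as a scalar multiplier on PIP2 production (sample kymographs;
# use `stenpol meanfield` for the bifurcation/threshold analysis).
model:
  feedback:
    actin_enabled: true
    a_act: 1.0
    myosin_enabled: true
    a_myo: 0.3
settings:
  duration: 1200.0
sweep:
  pip2_production_scale: [0.5, 0.8, 1.0, 2.0, 4.0]
n_replicates: 1
base_seed: 1
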