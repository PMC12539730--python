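# Baseline excitable network, no cytoskeletal feedback (4 replicates).
model: {}
settings:
  duration: 1200.0
n_replicates: 4
base_seed: 1
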