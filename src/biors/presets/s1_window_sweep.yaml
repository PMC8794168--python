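# RMHC efficiency vs window size W (search-space redundancy sweep).
fixture: {name: six_plus_four, n_domains: 4, window: 220}
mode: simple
engine:
  engine: rmhc
  nmut: 20
  eval_cap: 20000000
sweep:
  window: [10, 30, 70, 150, 220]
replicates: 50
base_seed: 404
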