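# RMHC efficiency vs mutation rate on the same 4-domain problem.
fixture: {name: six_plus_four, n_domains: 4, window: 220}
mode: simple
engine:
  engine: rmhc
  eval_cap: 20000000
sweep:
  nmut: [2, 6, 12, 20, 30, 60, 120, 240]
replicates: 200
base_seed: 402
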