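# GA efficiency vs mutation rate (mutations per chromosome), 4 domains of
# the 6+4 consensus, mu/lambda = 0.4: the low-sensitivity plateau sweep.
fixture: {name: six_plus_four, n_domains: 4, window: 220}
mode: simple
engine:
  engine: ga
  selection: mu_lambda
  mu_fraction: 0.4
  population_size: 600
  eval_cap: 20000000
sweep:
  nmut: [2, 6, 12, 20, 30, 60, 120]
replicates: 100
base_seed: 401
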