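# SELEX-efficiency benchmark row: mutation-only GA, (mu,lambda) selection,
# mu/lambda = 0.1, 8 domains of the 6+4 consensus, W = 220 (L = 1968).
fixture: {name: six_plus_four, n_domains: 8, window: 220}
mode: simple
engine:
  engine: ga
  selection: mu_lambda
  mu_fraction: 0.1
  population_size: 1000
  nmut: 12
  eval_cap: 200000000
replicates: 20
base_seed: 103
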