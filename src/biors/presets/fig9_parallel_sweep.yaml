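# Parallel RMHC: efficiency vs number of parallel climbers M at a mean
# mutation rate of 20 per chromosome.
fixture: {name: six_plus_four, n_domains: 4, window: 220}
mode: simple
engine:
  engine: parallel_rmhc
  nmut: 20
  eval_cap: 20000000
sweep:
  n_parallel: [1, 2, 5, 10, 20, 40, 80, 160, 320]
replicates: 100
base_seed: 403
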