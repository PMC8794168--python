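# Competitive staircase, single-point crossover GA: success rate vs
# crossover rate. Population size and mutation rate are choose-and-report
# (not fixed by the benchmark source); the values below are this
# package's defaults.
fixture: {name: ss_alt, n_domains: 4, window: 220}
mode: competitive
engine:
  engine: ga
  selection: sigma_scaling
  population_size: 1000
  nmut: 60
  crossover: single_point
  eval_cap: 2000000
sweep:
  crossover_rate: [0.0, 0.010, 0.025, 0.035, 0.050]
replicates: 40
base_seed: 201
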