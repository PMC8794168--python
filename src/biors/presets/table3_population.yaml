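# Segment recombination on the competitive staircase: population-size axis.
fixture: {name: ss_alt, n_domains: 4, window: 220}
mode: competitive
engine:
  engine: ga
  selection: sigma_scaling
  nmut: 60
  crossover: segment
  crossover_rate: 0.07
  eval_cap: 2000000
sweep:
  population_size: [2000, 4000, 6000]
replicates: 40
base_seed: 303
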