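# Segment recombination on the competitive staircase: mutation-rate axis.
fixture: {name: ss_alt, n_domains: 4, window: 220}
mode: competitive
engine:
  engine: ga
  selection: sigma_scaling
  population_size: 4000
  crossover: segment
  crossover_rate: 0.07
  eval_cap: 2000000
sweep:
  nmut: [60, 120, 180]
replicates: 40
base_seed: 301
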