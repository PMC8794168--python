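# Segment recombination on the competitive staircase: crossover-rate axis.
fixture: {name: ss_alt, n_domains: 4, window: 220}
mode: competitive
engine:
  engine: ga
  selection: sigma_scaling
  population_size: 4000
  nmut: 60
  crossover: segment
  eval_cap: 2000000
sweep:
  crossover_rate: [0.04, 0.07, 0.15]
replicates: 40
base_seed: 302
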