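# biors

Staircase fitness functions for simulating the *in vitro* directed
evolution of multidomain nucleic-acid devices, together with the heuristic
search algorithms used to benchmark them: mutation-only and crossover
genetic algorithms with (μ,λ) or sigma-scaling selection, random-mutation
hill climbing (RMHC, a (1+1) evolution strategy), and a
threshold-synchronized parallel RMHC.

The package is for people who study or plan SELEX-style experiments —
sequential selection of aptamer batteries, aptazymes and similar RNA/DNA
devices — and want to ask, *in silico*: how many candidate molecules must
be evaluated before all domains of a device are found, and which selection
scheme, mutation rate, population size, or recombination strategy gets
there cheapest?

## The model

A chromosome of length `L = N (c + W)` over `{A, C, G, U}` carries `N`
segments; segment `i` must come to contain one functional domain — a 26-nt
core matching a *consensus* with `u` uniquely defined positions and `d`
two-valued positions (either letter fits, only the preferred one scores).
The core may sit at any window offset `0..W−1` inside its segment. With
`g_i` the gradual increment of domain `i` (matched defined positions,
`0 ≤ g_i ≤ K = u + d`), the fitness of a sequence is the royal-staircase
form

    F = Δ · n_found + Σ_{i ≤ n_found} g_i ,        Δ = 100 ≫ K,

where `n_found` is the maximal prefix of segments holding a fitting core:
domains count only in strict left-to-right order. A uniform random
placement fits with probability `4^−u 2^−d` — 1 in 262 144 for the
Sassanfar–Szostak-motif-derived 4+10 consensus shipped as a fixture — so
each epoch of the search is a discovery lottery followed by gradual
refinement. Variants: *alternative structures* (the two-valued positions
split into rod/cloverleaf subsets `m1`, `m2`; a core scores
`max(s1, s2)`), and the *competitive* mode, where a domain only counts if
its predecessor folds as a rod — a cloverleaf blocks the staircase until
it is re-mutated.

## Worked example

Score a FASTA chromosome against the bundled simple consensus (4 unique
positions 2/6/12/25 = G, ten two-valued positions, `N = 4`, `W = 220`,
`Δ = 100`):

```
$ biors score --fasta worked.fasta --spec ss_simple_4_10
record	total	found_prefix	offsets	increments	structures
worked_example	110	1	1,.,.,.	10,0,0,0	.,.,.,.
```

The first segment holds the canonical example core
`NGGUGGGAACUGANNNNNNNNNNGGN` at window position 1: it fits the consensus,
10 of its 14 defined positions hold the preferred variant (increment 10),
and the block contributes `Δ + 10 = 110`. The other three segments contain
no fitting core, so they add nothing — with a staircase, downstream
domains are worthless until every upstream one is found.

Search for all four domains from a random start with hill climbing:

```python
from biors import EngineConfig, get_fixture, run_rmhc

fx = get_fixture("six_plus_four", n_domains=4)   # 6+4 consensus, W=220
cfg = EngineConfig(engine="rmhc", nmut=20, eval_cap=20_000_000)
out = run_rmhc(fx.layout, fx.spec, "simple", cfg, rng=1)
print(f"success={out.success} evaluations={out.evaluations}")
print("epoch transitions:", list(out.epoch_evals))
print("best fitness:", out.best_result.total, "found domains:", out.best_result.found_prefix)
```

```
success=True evaluations=14414
epoch transitions: [3007, 3730, 9613, 14414]
best fitness: 437 found domains: 4
```

14 414 candidate sequences were evaluated before all four domains were
found (the naive joint search space is `4^104 ≈ 10^62`); `epoch_evals`
records the evaluation count at which each next fitness level was first
reached.

Replicate batches and parameter sweeps run from bundled presets
(`biors presets --list`): the SELEX-efficiency table rows
(`table1_row_*`), competitive crossover and segment-recombination grids
(`table2_*`, `table3_*`), and mutation-rate / window / parallelism sweeps
(`fig7_*`, `fig8_*`, `fig9_*`, `s1_*`), e.g.

```
biors run --preset table1_row_p150 --scale 0.1 --out results/
```

writes `summary.tsv` (mean/SD evaluations over successful replicates,
success rate) and a `meta.json` sidecar with the config hash.

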