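# Methods

## The fitness family

`biors` models in-vitro directed evolution (SELEX-style selection cycles)
of multidomain nucleic-acid devices — batteries of aptamers, or
aptazyme-like sensor/effector assemblies — as heuristic search over
quaternary strings with a *biomolecular royal staircase* fitness function.
The chromosome of length `L = N × (core_length + W)` is divided into `N`
equal segments; each segment must come to contain one functional domain,
and domains only count in strict left-to-right order (a staircase, not a
royal road: a fit domain downstream of an unfit segment contributes
nothing).

A domain is not a single target string but a *consensus*: a set of
admissible cores defined by `u` uniquely required positions and `d`
two-valued (degenerate) positions, each of which accepts two letters but
only rewards the preferred one. For a core placement:

- if any defined position violates the consensus, the placement does not
  fit and scores 0 (the domain is "annihilated", never partially
  credited);
- otherwise the placement fits and its *gradual increment* `g` counts the
  matched unique positions (+1 each) and the two-valued positions holding
  their preferred letter (+1 each), so `0 ≤ g ≤ K = u + d`.

Within its segment the core may sit at any of the `W` window offsets
`0 .. W−1`; the scanner keeps the fitting placement of maximal increment,
breaking ties towards the leftmost offset (deterministic and
reproducible). The probability that a single uniform random placement fits
is exactly `4^−u · 2^−d` — for the Sassanfar–Szostak-derived 4+10 core,
one in 262 144 — which is why a windowed, consensus-based target is
searchable at all while a unique 26-mer would not be.

The total fitness is

```
F = Δ · n_found + Σ g_i  over the found prefix,
```

with the step `Δ = 100` chosen much larger than `K` so fitness levels of
successive epochs never overlap (`LayoutSpec` enforces `Δ > K`). The
*epoch* searching for domain `n+1` therefore has a flat discovery lottery
(no gradient until a core first fits) followed by gradual refinement.

### Alternative structures and competition

`AlternativeConsensusSpec` splits the two-valued positions into `m1`
(structure I, "rod") and `m2` (structure II, "cloverleaf"), two folds of
the same aptamer with a shared fit set. A fitting core gets structure
scores `s1` (uniques + m1 positions at their structure value) and `s2`
(uniques + m2 likewise); its increment is `max(s1, s2)` and it classifies
as rod when `s1 ≥ s2` (the tie goes to the structure that lets the
staircase continue; this tie-break is a declared design choice). In
*competitive* mode a domain only counts when the previously found domain
classifies rod — a cloverleaf predecessor sterically blocks everything
downstream. Gating is evaluated from the sequence alone on every call;
nothing is stored on the genome, so re-mutating a cloverleaf predecessor
into a rod immediately restores the longer prefix.

A consequence worth stating plainly: because the two structures share one
fit set and the increment is a maximum, any cloverleaf state is connected
to a rod state by single mutations along which the increment never
decreases (raise `s1` stepwise at constant maximum; from a tie, lower
`s2` one step at constant maximum). Equal-or-higher acceptance rules can
therefore always drift out of a cloverleaf "dead end" — the competitive
landscape is harder, but not absorbing. Search behaviour downstream of
this property is discussed under *Limitations*.

## Search engines

All engines measure cost in **fitness evaluations**: one count per
candidate chromosome whose fitness is computed, including the initial
population, stopping at the first evaluation that meets the success
criterion or at the evaluation cap. The default success criterion
`all_found` requires every domain found (`F ≥ NΔ`); `ideal` additionally
requires each domain's increment to reach a configured minimum.

- **GA** (`run_ga`): generational, no elitism. Selection is `(μ,λ)`
  truncation (the best `μ = mu_fraction·P` get `⌊λ/μ⌋` offspring slots
  each, remainder to the highest-ranked; ties broken stably) or *sigma
  scaling* (expected offspring `1 + (F_i − F̄)/2σ`; all 1 when `σ = 0`;
  clipped below at 0.1) realized by stochastic universal sampling, so
  realized counts differ from expectations by less than one. Optional
  crossover (single-point, two-point, or segment recombination) pairs the
  shuffled parents and recombines each pair with the configured rate,
  before mutation.
- **Point mutation** substitutes each position, independently with
  probability `Nmut/L`, by one of the three *other* letters, so the
  realized per-position change probability is exactly `Nmut/L` and the
  mean Hamming distance per application is exactly `Nmut`. Sampling is
  exact (binomial count, then a uniform subset), not approximate.
- **RMHC** (`run_rmhc`): (1+1) hill climbing; the mutant replaces the
  current sequence iff its fitness is *equal or higher*.
- **Parallel RMHC** (`run_parallel_rmhc`): `M` climbers step round-robin
  under a shared threshold that starts at `Δ`; when any climber reaches
  it, all `M` are replaced by copies of the current best and the threshold
  rises by `Δ` (skipping past the best fitness if a jump crossed several
  levels). Once a domain is found by anyone it is never lost by the
  ensemble. With `M = 1` the scheme reduces to RMHC.
- **Local mutagenesis** (optional, all engines): only the segment of the
  currently searched domain mutates; in competitive mode the previous
  domain's segment is also kept open, since continuing may require
  re-folding it. The rate stays `Nmut/L`.
- **Segment recombination** cuts only at a boundary of the last found
  segment (both boundaries equally likely; the right boundary is dropped
  when it coincides with the chromosome end), so found building blocks
  are exchanged whole.

The scoring scan, population evaluation, mutation, and the RMHC loops are
compiled with numba; every engine also has a pure-Python path (used
whenever a custom fitness callable is injected) implementing the same
acceptance and counting rules, which the tests use for evaluation-count
audits and as a cross-check of the compiled path. The two paths use
different RNG streams and agree in distribution, not draw-for-draw. All
randomness derives from the run seed; identical configuration and seed
give identical outcomes.

## Replication harness

`run_replicates` runs `R` seeded replicates (seed `base + i`) and reports
the benchmark-table quantities: mean and sample standard deviation
(`ddof = 1`) of evaluations **over successful replicates only**, plus the
success rate in percent — cap-outs lower the rate but never dilute the
mean, matching how a joint "mean + success rate" row must be read.
`sweep` runs cartesian grids with per-row seed blocks (offset `10^5` per
row index, so resuming an interrupted sweep reproduces the identical
table). Bundled presets cover the published benchmark rows: the
SELEX-efficiency table (8 domains of the 6+4 consensus, `W = 220`,
`L = 1968`, `(μ,λ)` with `μ/λ = 0.1`, `P ∈ {200000, 1000, 500, 250,
150}`, `Nmut ∈ {1, 12, 31, 62}`, cap 2×10⁸, 20 replicates), the
competitive crossover and segment-recombination tables, and the
mutation-rate / window / parallelism sweeps. The competitive tables'
population size and mutation rate are not fixed by the benchmark source;
the presets carry this package's choices and say so.

## Fixtures

Letters not pinned by the canonical worked examples are arbitrary fixed
choices documented in `fixtures.py`; a relabeling-invariance property
(fitness is equivariant under any consistent alphabet permutation of spec
and genome) guarantees search statistics do not depend on them. In the
two-structure fixture the non-contributing alternative at position 11 is
U — the printed pairing is inconsistent with the canonical worked core,
which carries U there and must fit. Sizes follow the benchmark: 26-nt
core, `W = 220`, `Δ = 100`, `N = 4` or 8.

## Problem sizes used by tests and acceptance checks

Property tests run on reduced cores (length ≤ 8) where enumeration is
exhaustive, and on the full `W = 220` layouts for the replication rows
(20 replicates each), the epoch-growth check (15 GA runs), the
mutation-rate response (grid {4, 12, 20, 30, 60}, 8 runs/point, cap
5×10⁶), the parallel-RMHC scaling (M ∈ {1, 64, 320}, 25 runs/point) and
the competitive comparisons (12 paired-seed runs/arm, cap 10⁶ at a
partial-success operating point calibrated on the no-crossover arm only:
sigma scaling, `P = 600`, `Nmut = 24`). The expected GA hitting time on
the one-base toy problem (8.5 evaluations) is a closed-form absorbing
Markov-chain result frozen into the test.

## Known limitations

- **Absolute evaluation counts.** The package reproduces the published
  benchmark's *relative* structure — row ordering, the optimal
  mutation-rate location near one mutation per `NK` defined positions,
  100% success, exponential epoch growth — but its absolute mean
  evaluation counts on the SELEX-efficiency rows are a near-constant
  factor ≈ N = 8 below the published means under the literal definitions
  implemented here (one count per candidate; per-position mutation
  probability `Nmut/L`). The corresponding replication test asserts the
  published absolute values and fails; the comparison is reported rather
  than absorbed into a fudge factor.
- **Competitive-staircase claims.** By the connectivity property above,
  equal-acceptance hill climbing cannot be permanently blocked by a
  cloverleaf predecessor, so the "hill climbing never reaches the 3rd
  domain" behaviour and the crossover/segment-recombination success-rate
  ordering do not reproduce under this scoring; the corresponding tests
  assert the published behaviour and fail. The competitive mode itself
  (gating, annihilation of downstream credit, restoration after
  re-folding) is implemented and tested.
- Rod/cloverleaf classes are purely consensus-defined; no secondary
  structure prediction, thermodynamics, binding kinetics, K_d, or
  background binding is modelled.
- The synthetic benchmark emulates idealized selection (exact truncation
  or sigma scaling, noiseless fitness); real SELEX rounds select through
  a stochastic binding-probability curve, so passing tests demonstrate
  algorithmic behaviour on the model landscape, not wet-lab effect sizes.
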