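"""Evolutionary search engines: mutation-only / crossover GA with (mu,lambda)
or sigma-scaling selection, random-mutation hill climbing (RMHC), and the
threshold-synchronized parallel RMHC.

Search cost is measured in *fitness evaluations*: every genome whose
fitness is computed — including the initial population — increments the
counter, and a run stops as soon as the success criterion is met or the
evaluation cap is reached.

Each engine has a compiled fast path (numba kernels) and a pure-Python
path. The Python path is selected by passing ``fitness_fn`` (any callable
``genome_codes -> (total, found_prefix, min_increment)``) and exists for
oracle cross-checks and evaluation-count audits; both paths implement the
same acceptance and counting rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from . import _kernels as K
from .consensus import LayoutSpec, decode_sequence
from .fitness import EncodedProblem, FitnessResult, Mode, biors_fitness

__all__ = [
    "EngineConfig",
    "SearchOutcome",
    "mu_lambda_select",
    "sigma_scaling_expected",
    "sus_sample",
    "run_ga",
    "run_rmhc",
    "run_parallel_rmhc",
    "run_search",
]

ENGINES = ("ga", "rmhc", "parallel_rmhc")
SELECTIONS = ("mu_lambda", "sigma_scaling")
CROSSOVERS = ("none", "single_point", "two_point", "segment")


@dataclass(frozen=True)
class EngineConfig:
    """Parameters of one search run.

    ``nmut`` is the mean number of mutations per chromosome per
    application (per-position rate nmut/L). ``mu_fraction`` is mu/lambda
    for truncation selection; ``n_parallel`` is the number of climbers M
    for parallel RMHC. ``success`` is "all_found" (every domain found,
    fitness >= N*delta) or "ideal" (additionally every domain's gradual
    increment >= ``min_increment``).
    """

    engine: str = "ga"
    population_size: int = 100
    mu_fraction: float = 0.1
    selection: str = "mu_lambda"
    crossover: str = "none"
    crossover_rate: float = 0.0
    nmut: float = 1.0
    local_mutagenesis: bool = False
    n_parallel: int = 1
    eval_cap: int = 200_000_000
    success: str = "all_found"
    min_increment: int = 0
    sigma_floor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}; expected one of {ENGINES}")
        if self.selection not in SELECTIONS:
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.crossover not in CROSSOVERS:
            raise ValueError(f"unknown crossover {self.crossover!r}")
        if not 0 < self.mu_fraction <= 1:
            raise ValueError("mu_fraction must be in (0, 1]")
        if self.population_size < 1 or self.n_parallel < 1 or self.eval_cap < 1:
            raise ValueError("population_size, n_parallel and eval_cap must be >= 1")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.success not in ("all_found", "ideal"):
            raise ValueError(f"unknown success criterion {self.success!r}")


@dataclass
class SearchOutcome:
    success: bool
    evaluations: int
    best_genome: str
    best_result: FitnessResult
    epoch_evals: tuple[int, ...]  # evaluation count at which prefix first hit 1..N (-1 = never)
    history: list = field(default_factory=list)  # (generation, evals, best_fit, best_prefix)


# ---------------------------------------------------------------- selection

def mu_lambda_select(fitnesses, mu: int) -> np.ndarray:
    """Truncation selection: indices of the lambda parent slots.

    The best mu individuals (stable order on ties) each receive
    floor(lambda/mu) slots; the lambda mod mu leftover slots go to the
    highest-ranked. Slots are returned in rank order.
    """
    f = np.asarray(fitnesses)
    lam = f.size
    if not 1 <= mu <= lam:
        raise ValueError(f"mu={mu} outside 1..{lam}")
    order = np.argsort(-f, kind="stable")[:mu]
    base, rem = divmod(lam, mu)
    counts = np.full(mu, base, dtype=np.int64)
    counts[:rem] += 1
    return np.repeat(order, counts)


def sigma_scaling_expected(fitnesses, floor: float = 0.1) -> np.ndarray:
    """Expected offspring counts e_i = 1 + (F_i - mean) / (2 sigma).

    With sigma = 0 every e_i is 1; values below ``floor`` are clipped up
    to it so even the worst individual keeps a small reproduction chance.
    """
    f = np.asarray(fitnesses, dtype=np.float64)
    if f.size == 0:
        raise ValueError("empty population")
    sigma = f.std()
    if sigma == 0:
        return np.ones(f.size)
    return np.maximum(1.0 + (f - f.mean()) / (2.0 * sigma), floor)


def sus_sample(expected, lam: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling: lambda parent indices whose realized
    counts differ from the (rescaled) expectations by less than 1."""
    e = np.asarray(expected, dtype=np.float64)
    cum = np.cumsum(e * (lam / e.sum()))
    points = rng.random() + np.arange(lam)
    return np.searchsorted(cum, points, side="right").clip(max=e.size - 1)


# ---------------------------------------------------------------- plumbing

def _as_rng(rng, cfg: EngineConfig) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(cfg.seed)
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng


def _min_inc(cfg: EngineConfig) -> int:
    return cfg.min_increment if cfg.success == "ideal" else 0


def _outcome(prob: EncodedProblem, g: np.ndarray, evals: int, cfg: EngineConfig,
             epoch_evals: np.ndarray, history: list) -> SearchOutcome:
    total, prefix, ming = prob.fitness_total(g)
    success = prefix == prob.layout.n_domains and ming >= _min_inc(cfg)
    detail = biors_fitness(g, prob.layout, prob.spec, prob.mode)
    return SearchOutcome(
        success=bool(success),
        evaluations=int(evals),
        best_genome=decode_sequence(g),
        best_result=detail,
        epoch_evals=tuple(int(x) for x in epoch_evals),
        history=history,
    )


def _mutation_span(prob: EncodedProblem, cfg: EngineConfig, prefix: int) -> tuple[int, int]:
    return K._mutation_range(cfg.local_mutagenesis, prob.mode_code, prefix,
                             prob.layout.n_domains, prob.layout.segment_length,
                             prob.layout.total_length)


def _python_mutate(g: np.ndarray, lo: int, hi: int, p: float, rng) -> np.ndarray:
    out = g.copy()
    hit = np.nonzero(rng.random(hi - lo) < p)[0] + lo
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


# ---------------------------------------------------------------- GA

def run_ga(layout: LayoutSpec, spec, mode: Mode, cfg: EngineConfig,
           rng=None, fitness_fn: Optional[Callable] = None) -> SearchOutcome:
    """Generational GA: evaluate, select, (recombine,) mutate, repeat.

    Selection is (mu,lambda) truncation or sigma scaling with SUS;
    offspring replace the whole population (no elitism). With
    ``cfg.crossover != "none"`` selected parents are shuffled, paired
    consecutively, and each pair recombines with ``cfg.crossover_rate``.
    """
    prob = EncodedProblem(layout, spec, mode)
    rng = _as_rng(rng, cfg)
    P = cfg.population_size
    L = layout.total_length
    N = layout.n_domains
    p = cfg.nmut / L
    if not 0 <= p <= 1:
        raise ValueError(f"nmut/L = {p} outside [0, 1]")
    min_inc = _min_inc(cfg)
    mu = max(1, round(cfg.mu_fraction * P))

    use_kernels = fitness_fn is None
    if use_kernels:
        K.seed_kernels(int(rng.integers(2 ** 31)))
    fit_fn = prob.fitness_total if fitness_fn is None else fitness_fn

    pop = rng.integers(0, 4, size=(P, L), dtype=np.uint8)
    fit = np.zeros(P, dtype=np.int64)
    pre = np.zeros(P, dtype=np.int64)
    mg = np.zeros(P, dtype=np.int64)
    epoch_evals = np.full(N, -1, dtype=np.int64)
    history: list = []
    evals = 0
    best_fit = -1
    best_genome = pop[0].copy()

    def evaluate() -> tuple[int, bool]:
        """Evaluate the population; returns (new eval count, success?)."""
        nonlocal best_fit, best_genome
        if use_kernels:
            K.eval_population(pop, *prob.kernel_args, fit, pre, mg)
            succ = (pre == N) & (mg >= min_inc)
            hits = np.nonzero(succ)[0]
            stop = int(hits[0]) if hits.size else -1
        else:
            stop = -1
            for i in range(P):
                fit[i], pre[i], mg[i] = fit_fn(pop[i])
                if pre[i] == N and mg[i] >= min_inc:
                    stop = i
                    break
                if evals + i + 1 >= cfg.eval_cap:
                    stop = -2  # cap hit mid-generation
                    fit[i + 1:] = -1
                    break
        if stop >= 0 and evals + stop + 1 <= cfg.eval_cap:
            n = evals + stop + 1
            ok = True
        else:
            n = min(evals + P, cfg.eval_cap)
            ok = False
        top = int(np.argmax(fit))
        if fit[top] > best_fit:
            best_fit = int(fit[top])
            best_genome = pop[top].copy()
        pmax = int(pre.max())
        for q in range(pmax):
            if epoch_evals[q] < 0:
                epoch_evals[q] = n
        return n, ok

    gen = 0
    while True:
        evals, done = evaluate()
        history.append((gen, evals, int(fit.max()), int(pre.max())))
        if done or evals >= cfg.eval_cap:
            break
        # --- selection
        if cfg.selection == "mu_lambda":
            parents = mu_lambda_select(fit, mu)
        else:
            parents = sus_sample(sigma_scaling_expected(fit, cfg.sigma_floor), P, rng)
        parents = parents[rng.permutation(P)]
        offspring = pop[parents].copy()
        # --- crossover
        if cfg.crossover != "none" and cfg.crossover_rate > 0:
            seg = layout.segment_length
            lf = max(int(pre.max()), 1)
            for j in np.nonzero(rng.random(P // 2) < cfg.crossover_rate)[0]:
                a, b = 2 * j, 2 * j + 1
                if cfg.crossover == "single_point":
                    cuts = [int(rng.integers(1, L))]
                elif cfg.crossover == "two_point":
                    cuts = sorted(rng.choice(np.arange(1, L), size=2, replace=False).tolist())
                else:  # segment recombination at a boundary of the last found segment
                    pts = [k for k in ((lf - 1) * seg, lf * seg) if 1 <= k <= L - 1]
                    cuts = [pts[int(rng.integers(0, len(pts)))]]
                for k in cuts:
                    tmp = offspring[a, k:].copy()
                    offspring[a, k:] = offspring[b, k:]
                    offspring[b, k:] = tmp
        # --- mutation
        lo, hi = _mutation_span(prob, cfg, int(pre.max()))
        if use_kernels:
            allowed = np.arange(lo, hi, dtype=np.int64)
            K.mutate_rows(offspring, p, allowed, allowed.copy())
        else:
            for i in range(P):
                offspring[i] = _python_mutate(offspring[i], lo, hi, p, rng)
        pop = offspring
        gen += 1

    return _outcome(prob, best_genome, evals, cfg, epoch_evals, history)


# ---------------------------------------------------------------- RMHC

def run_rmhc(layout: LayoutSpec, spec, mode: Mode, cfg: EngineConfig,
             rng=None, fitness_fn: Optional[Callable] = None) -> SearchOutcome:
    """(1+1) hill climbing: mutate every position with probability nmut/L,
    keep the mutant iff its fitness is equal or higher."""
    prob = EncodedProblem(layout, spec, mode)
    rng = _as_rng(rng, cfg)
    L = layout.total_length
    N = layout.n_domains
    p = cfg.nmut / L
    if not 0 <= p <= 1:
        raise ValueError(f"nmut/L = {p} outside [0, 1]")
    min_inc = _min_inc(cfg)
    g = rng.integers(0, 4, size=L, dtype=np.uint8)
    epoch_evals = np.full(N, -1, dtype=np.int64)
    history: list = []

    if fitness_fn is None:
        K.seed_kernels(int(rng.integers(2 ** 31)))
        evals, _, _ = K.rmhc(g, p, cfg.local_mutagenesis, cfg.eval_cap, min_inc,
                             *prob.kernel_args, epoch_evals,
                             np.empty(L, dtype=np.int64), np.empty(L, dtype=np.uint8))
        return _outcome(prob, g, evals, cfg, epoch_evals, history)

    cur_fit, cur_pre, cur_mg = fitness_fn(g)
    evals = 1
    for q in range(cur_pre):
        if epoch_evals[q] < 0:
            epoch_evals[q] = evals
    history.append((0, evals, int(cur_fit), int(cur_pre)))
    step = 0
    while not (cur_pre == N and cur_mg >= min_inc) and evals < cfg.eval_cap:
        step += 1
        lo, hi = _mutation_span(prob, cfg, cur_pre)
        cand = _python_mutate(g, lo, hi, p, rng)
        f, pf, mgv = fitness_fn(cand)
        evals += 1
        if f >= cur_fit:
            g, cur_fit, cur_pre, cur_mg = cand, f, pf, mgv
            for q in range(pf):
                if epoch_evals[q] < 0:
                    epoch_evals[q] = evals
            history.append((step, evals, int(cur_fit), int(cur_pre)))
    return _outcome(prob, g, evals, cfg, epoch_evals, history)


# ---------------------------------------------------------------- parallel RMHC

def run_parallel_rmhc(layout: LayoutSpec, spec, mode: Mode, cfg: EngineConfig,
                      rng=None, fitness_fn: Optional[Callable] = None,
                      _capture_syncs: Optional[list] = None) -> SearchOutcome:
    """M independent climbers with threshold synchronization.

    The acceptance threshold starts at delta; whenever a climber reaches
    it, every climber is replaced by a copy of the current best and the
    threshold rises by delta, so once a domain is found it is never lost
    across the ensemble. Evaluations are summed over all climbers.
    """
    prob = EncodedProblem(layout, spec, mode)
    rng = _as_rng(rng, cfg)
    L = layout.total_length
    N = layout.n_domains
    M = cfg.n_parallel
    delta = layout.delta
    p = cfg.nmut / L
    if not 0 <= p <= 1:
        raise ValueError(f"nmut/L = {p} outside [0, 1]")
    min_inc = _min_inc(cfg)
    pop = rng.integers(0, 4, size=(M, L), dtype=np.uint8)
    epoch_evals = np.full(N, -1, dtype=np.int64)
    history: list = []

    if fitness_fn is None and _capture_syncs is None:
        K.seed_kernels(int(rng.integers(2 ** 31)))
        evals, _, _, b = K.parallel_rmhc(pop, p, cfg.local_mutagenesis, cfg.eval_cap,
                                         min_inc, *prob.kernel_args, epoch_evals,
                                         np.empty(L, dtype=np.int64),
                                         np.empty(L, dtype=np.uint8))
        return _outcome(prob, pop[b], evals, cfg, epoch_evals, history)

    fit_fn = prob.fitness_total if fitness_fn is None else fitness_fn
    fits = np.empty(M, dtype=np.int64)
    pres = np.empty(M, dtype=np.int64)
    mgs = np.empty(M, dtype=np.int64)
    evals = 0
    for m in range(M):
        fits[m], pres[m], mgs[m] = fit_fn(pop[m])
        evals += 1
        for q in range(pres[m]):
            if epoch_evals[q] < 0:
                epoch_evals[q] = evals
    threshold = delta
    done = False
    while not done:
        restart = False
        for m in range(M):
            if evals >= cfg.eval_cap:
                done = True
                break
            lo, hi = _mutation_span(prob, cfg, int(pres[m]))
            cand = _python_mutate(pop[m], lo, hi, p, rng)
            f, pf, mgv = fit_fn(cand)
            evals += 1
            if f >= fits[m]:
                pop[m], fits[m], pres[m], mgs[m] = cand, f, pf, mgv
                for q in range(pf):
                    if epoch_evals[q] < 0:
                        epoch_evals[q] = evals
            if pres[m] == N and mgs[m] >= min_inc:
                done = True
                break
            if fits[m] >= threshold:
                b = int(np.argmax(fits))
                pop[:] = pop[b]
                fits[:] = fits[b]
                pres[:] = pres[b]
                mgs[:] = mgs[b]
                while threshold <= fits[b]:
                    threshold += delta
                if _capture_syncs is not None:
                    _capture_syncs.append(pop.copy())
                history.append(("sync", evals, int(fits[b]), int(pres[b])))
                restart = True
                break
        if not restart and not done:
            continue
    b = int(np.argmax(fits))
    return _outcome(prob, pop[b], evals, cfg, epoch_evals, history)


# ---------------------------------------------------------------- dispatch

def run_search(layout: LayoutSpec, spec, mode: Mode, cfg: EngineConfig,
               rng=None, fitness_fn: Optional[Callable] = None) -> SearchOutcome:
    """Dispatch to the engine named in ``cfg.engine``."""
    fn = {"ga": run_ga, "rmhc": run_rmhc, "parallel_rmhc": run_parallel_rmhc}[cfg.engine]
    return fn(layout, spec, mode, cfg, rng=rng, fitness_fn=fitness_fn)
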