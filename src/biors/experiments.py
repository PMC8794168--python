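"""Replicate batches, summary tables, and parameter sweeps.

A :class:`RunSummary` reports search cost the way the benchmark tables
do: the mean and sample standard deviation (n-1) of the evaluation count
over *successful* replicates, alongside the success rate in percent.
Cap-outs therefore never dilute the mean; they only lower the rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import AlternativeConsensusSpec, ConsensusSpec, LayoutSpec
from .engines import EngineConfig, SearchOutcome, run_search
from .fixtures import Fixture, get_fixture

__all__ = [
    "ExperimentSpec",
    "RunSummary",
    "run_replicates",
    "sweep",
    "analytic_counts",
]

# engine-config fields a sweep axis may vary, plus the layout window
_SWEEPABLE = {"nmut", "population_size", "crossover_rate", "n_parallel",
              "mu_fraction", "eval_cap", "window", "crossover"}


@dataclass(frozen=True)
class ExperimentSpec:
    """A replicate batch: fixture + engine config + R seeded repeats.

    ``sweep_axes`` maps parameter names (engine fields or ``window``) to
    value lists; the grid is the cartesian product. Replicate ``i`` of a
    row runs with seed ``base_seed + i``; rows are offset by 10^5 so their
    seed blocks never overlap.
    """

    fixture: str | Fixture
    engine: EngineConfig
    replicates: int = 20
    base_seed: int = 0
    mode: Optional[str] = None
    sweep_axes: Mapping[str, Sequence] = field(default_factory=dict)
    engine_fn: Optional[Callable] = None  # test injection: (layout, spec, mode, cfg, rng) -> SearchOutcome

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name, values in self.sweep_axes.items():
            if name not in _SWEEPABLE:
                raise ValueError(f"cannot sweep {name!r}; allowed: {sorted(_SWEEPABLE)}")
            if len(values) == 0:
                raise ValueError(f"sweep axis {name!r} is empty")

    def resolved(self) -> tuple[Fixture, str]:
        fx = get_fixture(self.fixture) if isinstance(self.fixture, str) else self.fixture
        return fx, self.mode or fx.default_mode


@dataclass(frozen=True)
class RunSummary:
    """Aggregate of one replicate batch."""

    evaluations: tuple[int, ...]
    successes: tuple[bool, ...]
    mean_evaluations: float  # over successful replicates (nan if none)
    sd_evaluations: float    # sample SD, ddof=1 (nan if < 2 successes)
    success_rate: float      # percent
    replicates: int

    @classmethod
    def from_runs(cls, evals: Sequence[int], succ: Sequence[bool]) -> "RunSummary":
        evals = tuple(int(e) for e in evals)
        succ = tuple(bool(s) for s in succ)
        ok = np.array([e for e, s in zip(evals, succ) if s], dtype=float)
        return cls(
            evaluations=evals,
            successes=succ,
            mean_evaluations=float(ok.mean()) if ok.size else float("nan"),
            sd_evaluations=float(ok.std(ddof=1)) if ok.size > 1 else float("nan"),
            success_rate=100.0 * sum(succ) / len(succ),
            replicates=len(succ),
        )


def run_replicates(spec: ExperimentSpec) -> RunSummary:
    """Run R independent seeded replicates and aggregate them."""
    fx, mode = spec.resolved()
    evals, succ = [], []
    for i in range(spec.replicates):
        seed = spec.base_seed + i
        cfg = replace(spec.engine, seed=seed)
        if spec.engine_fn is not None:
            out = spec.engine_fn(fx.layout, fx.spec, mode, cfg, seed)
        else:
            out = run_search(fx.layout, fx.spec, mode, cfg, rng=seed)
        evals.append(out.evaluations)
        succ.append(out.success)
    return RunSummary.from_runs(evals, succ)


def _apply_point(spec: ExperimentSpec, point: Mapping) -> ExperimentSpec:
    fx, _ = spec.resolved()
    engine_over = {k: v for k, v in point.items() if k != "window"}
    if "window" in point:
        fx = fx.with_layout(window=int(point["window"]))
    return replace(spec, fixture=fx, engine=replace(spec.engine, **engine_over))


def _row_key(point: Mapping) -> str:
    return ";".join(f"{k}={point[k]}" for k in sorted(point))


def sweep(spec: ExperimentSpec, out_path: str | Path | None = None) -> pd.DataFrame:
    """Run the cartesian grid of ``spec.sweep_axes``.

    With ``out_path`` the summary table (TSV) is written row by row as
    rows complete; rows already present in the file are skipped, so an
    interrupted sweep resumes to an identical table (seeds are derived
    from the row's grid index, not from completion order).
    """
    axes = dict(spec.sweep_axes)
    names = sorted(axes)
    grid = list(itertools.product(*(axes[n] for n in names))) if names else [()]
    done: dict[str, dict] = {}
    path = Path(out_path) if out_path is not None else None
    if path is not None and path.exists():
        prev = pd.read_csv(path, sep="\t")
        done = {r["key"]: r for _, r in prev.iterrows()}
    rows = []
    for idx, values in enumerate(grid):
        point = dict(zip(names, values))
        key = _row_key(point)
        if key in done:
            rows.append(dict(done[key]))
            continue
        sub = _apply_point(spec, point)
        sub = replace(sub, base_seed=spec.base_seed + 100_000 * idx)
        summary = run_replicates(sub)
        fx, mode = sub.resolved()
        row = {
            "key": key,
            **point,
            "fixture": fx.name,
            "mode": mode,
            "engine": sub.engine.engine,
            "P": sub.engine.population_size,
            "nmut": sub.engine.nmut,
            "crossover": sub.engine.crossover,
            "crossover_rate": sub.engine.crossover_rate,
            "W": fx.layout.window,
            "N": fx.layout.n_domains,
            "R": sub.replicates,
            "cap": sub.engine.eval_cap,
            "mean_evals": summary.mean_evaluations,
            "sd_evals": summary.sd_evaluations,
            "success_rate": summary.success_rate,
            "seed": sub.base_seed,
        }
        rows.append(row)
        if path is not None:
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return pd.DataFrame(rows)


def analytic_counts(spec, layout: LayoutSpec) -> dict[str, int]:
    """Exact combinatorial sizes of the search problem.

    ``search_space_per_domain`` = 4^u * 2^d for u unique and d two-valued
    positions: the reciprocal of the probability that a uniform random
    core placement fits the consensus (one admissible choice of the
    defined positions per 4^u * 2^d candidates);
    ``naive_total_space`` = 4^(core_length * N), the brute-force space of
    all N cores jointly, in exact integer arithmetic.
    """
    if isinstance(spec, AlternativeConsensusSpec):
        u, d = len(spec.unique), len(spec.m1) + len(spec.m2)
    elif isinstance(spec, ConsensusSpec):
        u, d = len(spec.unique), len(spec.two_valued)
    else:
        raise TypeError(f"unsupported spec type {type(spec).__name__}")
    return {
        "search_space_per_domain": 4 ** u * 2 ** d,
        "total_length": layout.total_length,
        "naive_total_space": 4 ** (layout.core_length * layout.n_domains),
    }
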