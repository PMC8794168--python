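"""Variation operators: point mutation, crossover variants, segment
recombination and local-mutagenesis masks.

All operators are pure (inputs are never modified) and deterministic under
a seeded ``numpy.random.Generator``. Sequences may be passed as strings or
uint8 code arrays; the output type follows the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .consensus import LayoutSpec, decode_sequence, encode_sequence

__all__ = [
    "MutationConfig",
    "point_mutate",
    "single_point_crossover",
    "two_point_crossover",
    "segment_recombination",
    "local_mutation_mask",
]


@dataclass(frozen=True)
class MutationConfig:
    """Mean number of mutations per chromosome per application.

    The per-position substitution probability is ``nmut / L`` where L is
    the chromosome length; ``mask`` (boolean, length L) restricts which
    positions may mutate — the rate itself stays relative to L, matching
    local mutagenesis of a subsequence.
    """

    nmut: float
    mask: Optional[np.ndarray] = None

    def rate(self, length: int) -> float:
        p = self.nmut / length
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"per-position mutation probability {p} outside [0, 1]")
        return p


def _coerce(seq):
    if isinstance(seq, np.ndarray):
        return encode_sequence(seq), False
    return encode_sequence(seq), True


def _emit(codes: np.ndarray, as_str: bool):
    return decode_sequence(codes) if as_str else codes


def point_mutate(genome, cfg: MutationConfig, rng: np.random.Generator):
    """Substitute each mutable position, with probability ``nmut/L``, by a
    symbol drawn uniformly from the three *other* symbols."""
    g, as_str = _coerce(genome)
    p = cfg.rate(g.size)
    hit = rng.random(g.size) < p
    if cfg.mask is not None:
        mask = np.asarray(cfg.mask, dtype=bool)
        if mask.size != g.size:
            raise ValueError(f"mask length {mask.size} != genome length {g.size}")
        hit &= mask
    out = g.copy()
    idx = np.nonzero(hit)[0]
    if idx.size:
        # +1..+3 mod 4 is a uniform draw over the three other symbols
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return _emit(out, as_str)


def _check_pair(p1, p2):
    g1, s1 = _coerce(p1)
    g2, s2 = _coerce(p2)
    if g1.size != g2.size:
        raise ValueError(f"parent lengths differ: {g1.size} != {g2.size}")
    if g1.size < 2:
        raise ValueError("crossover needs chromosomes of length >= 2")
    return g1, g2, s1 and s2


def _cut(g1, g2, k):
    c1 = np.concatenate([g1[:k], g2[k:]])
    c2 = np.concatenate([g2[:k], g1[k:]])
    return c1, c2


def single_point_crossover(p1, p2, rng: np.random.Generator):
    """Exchange tails after a cut site drawn uniformly from 1..L-1."""
    g1, g2, as_str = _check_pair(p1, p2)
    k = int(rng.integers(1, g1.size))
    c1, c2 = _cut(g1, g2, k)
    return _emit(c1, as_str), _emit(c2, as_str)


def two_point_crossover(p1, p2, rng: np.random.Generator):
    """Exchange the middle block between two distinct cut sites."""
    g1, g2, as_str = _check_pair(p1, p2)
    if g1.size < 3:
        raise ValueError("two-point crossover needs chromosomes of length >= 3")
    k1, k2 = sorted(rng.choice(np.arange(1, g1.size), size=2, replace=False).tolist())
    c1 = g1.copy()
    c2 = g2.copy()
    c1[k1:k2] = g2[k1:k2]
    c2[k1:k2] = g1[k1:k2]
    return _emit(c1, as_str), _emit(c2, as_str)


def allowed_recombination_points(layout: LayoutSpec, last_found: int) -> list[int]:
    """Valid cut sites for segment recombination: the boundaries of the
    last found segment, restricted to genuine cut sites 1..L-1.

    ``last_found`` is 1-based; when it equals ``n_domains`` the right
    boundary coincides with the chromosome end and is dropped (a cut there
    would be a no-op).
    """
    if not 1 <= last_found <= layout.n_domains:
        raise ValueError(f"last_found {last_found} outside 1..{layout.n_domains}")
    s = layout.segment_length
    L = layout.total_length
    return [k for k in ((last_found - 1) * s, last_found * s) if 1 <= k <= L - 1]


def segment_recombination(p1, p2, layout: LayoutSpec, last_found: int,
                          rng: np.random.Generator):
    """Single-point crossover with the cut site restricted to a boundary of
    the last found segment, so found building blocks are exchanged whole."""
    g1, g2, as_str = _check_pair(p1, p2)
    if g1.size != layout.total_length:
        raise ValueError(f"parent length {g1.size} != layout total length {layout.total_length}")
    points = allowed_recombination_points(layout, last_found)
    k = points[int(rng.integers(0, len(points)))]
    c1, c2 = _cut(g1, g2, k)
    return _emit(c1, as_str), _emit(c2, as_str)


def local_mutation_mask(layout: LayoutSpec, epoch: int, competitive: bool = False) -> np.ndarray:
    """Boolean mask opening only the segment searched in ``epoch`` (1-based).

    In competitive mode the segment of the previously found domain is also
    opened: continuing the staircase may require re-folding that domain to
    its rod structure.
    """
    if not 1 <= epoch <= layout.n_domains:
        raise ValueError(f"epoch {epoch} outside 1..{layout.n_domains}")
    mask = np.zeros(layout.total_length, dtype=bool)
    lo, hi = layout.segment_bounds(epoch - 1)
    if competitive and epoch > 1:
        lo, _ = layout.segment_bounds(epoch - 2)
    mask[lo:hi] = True
    return mask
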