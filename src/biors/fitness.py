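"""Staircase fitness evaluation of chromosomes against consensus specs.

The fitness of a chromosome of ``N`` segments is::

    F = delta * n_found + sum(g_i for the found prefix)

where ``n_found`` is the length of the maximal prefix of segments holding a
fitting core placement (searched inside each segment over window offsets
0..W-1), and ``g_i`` is the gradual increment of domain ``i`` — the number
of defined positions holding the preferred / structure variant. Domains
downstream of the first failure contribute nothing even if their segments
fit: blocks only count in strict left-to-right order. In *competitive*
mode a domain additionally only counts when the previously found domain
classifies as the rod structure (s1 >= s2); a cloverleaf predecessor
blocks the rest of the staircase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from . import _kernels as K
from .consensus import (AlternativeConsensusSpec, ConsensusSpec, LayoutSpec,
                        encode_sequence)

__all__ = [
    "Mode",
    "DomainResult",
    "FitnessResult",
    "score_core_simple",
    "score_core_alternative",
    "classify_structure",
    "scan_window",
    "biors_fitness",
    "EncodedProblem",
]

Mode = Literal["simple", "alternative", "competitive"]
_MODES = {"simple": K.MODE_SIMPLE, "alternative": K.MODE_ALTERNATIVE,
          "competitive": K.MODE_COMPETITIVE}

ROD = "rod"
CLOVERLEAF = "cloverleaf"


@dataclass(frozen=True)
class DomainResult:
    """Diagnostics for one segment: did its domain count, and where."""
    found: bool
    increment: int
    offset: Optional[int]
    structure: Optional[str]  # "rod" | "cloverleaf" | None


@dataclass(frozen=True)
class FitnessResult:
    total: int
    found_prefix: int
    per_domain: tuple[DomainResult, ...]


def _encode_core(core, spec) -> np.ndarray:
    g = encode_sequence(core)
    if g.size != spec.core_length:
        raise ValueError(f"core length {g.size} != spec core length {spec.core_length}")
    return g


def score_core_simple(core, spec: ConsensusSpec) -> tuple[bool, int]:
    """Score one core placement against a simple consensus.

    Returns ``(fits, increment)``: the core fits iff every unique position
    holds its required value and every two-valued position one of its two
    values; the increment counts unique matches (+1 each) plus two-valued
    positions holding the preferred variant (+1 each). A non-fitting core
    scores 0 (the domain is annihilated, not partially credited).
    """
    if not isinstance(spec, ConsensusSpec):
        raise TypeError("score_core_simple needs a ConsensusSpec")
    g = _encode_core(core, spec)
    upos, uval, tpos, tpref, talt = spec.encoded()
    fits, inc, _ = K.scan_simple(g, 0, 1, upos, uval, tpos, tpref, talt)
    return bool(fits), int(inc)


def score_core_alternative(core, spec: AlternativeConsensusSpec) -> tuple[bool, int, int, int]:
    """Score one core against the two-structure consensus.

    Returns ``(fits, increment, s1, s2)`` where ``s1``/``s2`` count unique
    matches plus m1/m2 positions at their structure value, and
    ``increment = max(s1, s2)``. A non-fitting core scores (False, 0, 0, 0).
    """
    if not isinstance(spec, AlternativeConsensusSpec):
        raise TypeError("score_core_alternative needs an AlternativeConsensusSpec")
    g = _encode_core(core, spec)
    enc = spec.encoded()
    fits, inc, _, s1, s2 = K.scan_alternative(g, 0, 1, *enc)
    return bool(fits), int(inc), int(s1), int(s2)


def classify_structure(core, spec: AlternativeConsensusSpec) -> str:
    """Classify a *fitting* core as "rod" (s1 >= s2) or "cloverleaf".

    The tie goes to the rod, the structure that permits the staircase to
    continue. Raises ``ValueError`` when the core does not fit.
    """
    fits, _, s1, s2 = score_core_alternative(core, spec)
    if not fits:
        raise ValueError("classify_structure called on a core that does not fit the consensus")
    return ROD if s1 >= s2 else CLOVERLEAF


def scan_window(segment, spec, n_offsets: int | None = None):
    """Find the best core placement inside a segment.

    Placements at 0-based offsets ``0..W-1`` (``W = len(segment) -
    core_length`` by default) are scored; the fitting placement with the
    largest increment wins, ties broken by the smallest offset. Returns
    ``(fits, increment, offset)`` with ``offset=None`` when nothing fits.
    """
    g = encode_sequence(segment)
    if g.size < spec.core_length:
        raise ValueError(f"segment of length {g.size} is shorter than the core ({spec.core_length})")
    if n_offsets is None:
        n_offsets = max(g.size - spec.core_length, 1)
    if n_offsets < 1 or n_offsets + spec.core_length > g.size + 1:
        raise ValueError("n_offsets places the core outside the segment")
    if isinstance(spec, AlternativeConsensusSpec):
        fits, inc, off, _, _ = K.scan_alternative(g, 0, n_offsets, *spec.encoded())
    elif isinstance(spec, ConsensusSpec):
        fits, inc, off = K.scan_simple(g, 0, n_offsets, *spec.encoded())
    else:
        raise TypeError(f"unsupported spec type {type(spec).__name__}")
    return bool(fits), int(inc), (int(off) if fits else None)


class EncodedProblem:
    """A (layout, consensus, mode) triple encoded for the compiled kernels.

    Used by the search engines; the ``kernel_args`` tuple is passed
    verbatim to every kernel after the genome/population argument.
    """

    def __init__(self, layout: LayoutSpec, spec, mode: Mode):
        if mode not in _MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(_MODES)}")
        if mode == "simple" and not isinstance(spec, ConsensusSpec):
            raise TypeError("mode='simple' needs a ConsensusSpec")
        if mode in ("alternative", "competitive") and not isinstance(spec, AlternativeConsensusSpec):
            raise TypeError(f"mode={mode!r} needs an AlternativeConsensusSpec")
        layout.validate_spec(spec)
        self.layout = layout
        self.spec = spec
        self.mode = mode
        self.mode_code = _MODES[mode]
        if isinstance(spec, ConsensusSpec):
            upos, uval, tpos, tpref, talt = spec.encoded()
            m1pos = m2pos = K._EMPTY_POS
            m1val = m1alt = m2val = m2alt = K._EMPTY_VAL
        else:
            upos, uval, m1pos, m1val, m1alt, m2pos, m2val, m2alt = spec.encoded()
            tpos, tpref, talt = K._EMPTY_POS, K._EMPTY_VAL, K._EMPTY_VAL
        self.kernel_args = (
            self.mode_code, layout.n_domains, layout.segment_length,
            layout.window, layout.delta,
            upos, uval, tpos, tpref, talt,
            m1pos, m1val, m1alt, m2pos, m2val, m2alt,
        )

    @property
    def target_fitness(self) -> int:
        return self.layout.n_domains * self.layout.delta

    def fitness_total(self, g: np.ndarray) -> tuple[int, int, int]:
        """(total, found_prefix, min increment over the prefix)."""
        return K.fitness_total(g, *self.kernel_args)


def biors_fitness(genome, layout: LayoutSpec, spec, mode: Mode = "simple") -> FitnessResult:
    """Evaluate the staircase fitness of a whole chromosome.

    ``genome`` must have length ``layout.total_length``; ``spec`` is a
    :class:`ConsensusSpec` (mode "simple") or
    :class:`AlternativeConsensusSpec` (modes "alternative"/"competitive").
    """
    prob = EncodedProblem(layout, spec, mode)
    g = encode_sequence(genome)
    if g.size != layout.total_length:
        raise ValueError(f"genome length {g.size} != layout total length {layout.total_length}")
    W = layout.window
    seg = layout.segment_length
    enc = spec.encoded()
    domains: list[DomainResult] = []
    total = 0
    prefix = 0
    prev_rod = True
    broken = False
    for i in range(layout.n_domains):
        start = i * seg
        if broken:
            domains.append(DomainResult(False, 0, None, None))
            continue
        if mode == "simple":
            fits, inc, off = K.scan_simple(g, start, W, *enc)
            s1, s2 = 1, 0
            structure = None
        else:
            fits, inc, off, s1, s2 = K.scan_alternative(g, start, W, *enc)
            structure = (ROD if s1 >= s2 else CLOVERLEAF) if fits else None
        if not fits or (mode == "competitive" and i > 0 and not prev_rod):
            broken = True
            domains.append(DomainResult(False, 0, None, None))
            continue
        prefix += 1
        total += layout.delta + inc
        prev_rod = s1 >= s2
        domains.append(DomainResult(True, int(inc), int(off), structure))
    return FitnessResult(total=int(total), found_prefix=prefix, per_domain=tuple(domains))
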