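"""Consensus specifications and problem geometry for staircase fitness functions.

A *consensus* describes the family of sequences accepted as a functional
domain (e.g. an ATP-binding aptamer core): some positions are uniquely
defined, others may take one of two values, of which one (the *preferred*
variant) contributes an extra fitness unit. A :class:`LayoutSpec` describes
how ``n_domains`` such cores are laid out on a chromosome, each inside a
segment of ``core_length + window`` nucleotides, with a fitness step
``delta`` awarded per found domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ALPHABET",
    "encode_sequence",
    "decode_sequence",
    "ConsensusSpec",
    "AlternativeConsensusSpec",
    "LayoutSpec",
]

#: RNA alphabet used throughout; DNA input is accepted (T is read as U).
ALPHABET = "ACGU"

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["T"] = _CODE["U"]

# fast byte-level lookup table: 255 marks an invalid symbol
_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def encode_sequence(seq: str | bytes | np.ndarray) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array (A,C,G,U -> 0..3).

    T/t is normalized to U. Raises ``ValueError`` on any other symbol.
    """
    if isinstance(seq, np.ndarray):
        if seq.dtype == np.uint8 and seq.size and seq.max(initial=0) < 4:
            return np.ascontiguousarray(seq)
        raise ValueError("array genomes must be uint8 codes in 0..3")
    raw = seq.encode() if isinstance(seq, str) else bytes(seq)
    codes = _LUT[np.frombuffer(raw, dtype=np.uint8)]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"invalid symbol {chr(raw[i])!r} at position {i + 1}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; always writes U, never T."""
    return "".join(ALPHABET[c] for c in np.asarray(codes, dtype=np.uint8))


def _validate_base(b: str, where: str) -> str:
    b = b.upper().replace("T", "U")
    if b not in _CODE or len(b) != 1:
        raise ValueError(f"{where}: {b!r} is not a nucleotide")
    return b


def _check_positions(positions, core_length: int, what: str) -> None:
    for p in positions:
        if not (1 <= int(p) <= core_length):
            raise ValueError(f"{what} position {p} outside 1..{core_length}")


@dataclass(frozen=True)
class ConsensusSpec:
    """Simple consensus: uniquely defined plus two-valued (degenerate) positions.

    Parameters
    ----------
    core_length:
        Number of nucleotides in the domain core (26 for the
        Sassanfar–Szostak-derived fixtures).
    unique:
        1-based core position -> required nucleotide. A mismatch at any of
        these annihilates the domain (it is "not found").
    two_valued:
        1-based core position -> (preferred, alternative). Either value
        fits the consensus, but only the preferred one adds +1 to the
        gradual fitness increment.
    """

    core_length: int
    unique: Mapping[int, str]
    two_valued: Mapping[int, tuple[str, str]]

    def __post_init__(self):
        if self.core_length < 1:
            raise ValueError("core_length must be positive")
        unique = {int(p): _validate_base(b, f"unique[{p}]") for p, b in self.unique.items()}
        two = {}
        for p, pair in self.two_valued.items():
            a, b = pair
            a = _validate_base(a, f"two_valued[{p}]")
            b = _validate_base(b, f"two_valued[{p}]")
            if a == b:
                raise ValueError(f"two_valued[{p}]: values must differ")
            two[int(p)] = (a, b)
        _check_positions(unique, self.core_length, "unique")
        _check_positions(two, self.core_length, "two_valued")
        if set(unique) & set(two):
            raise ValueError("unique and two-valued position sets overlap")
        object.__setattr__(self, "unique", unique)
        object.__setattr__(self, "two_valued", two)

    @property
    def n_defined(self) -> int:
        """K, the number of defined positions (= maximum gradual increment)."""
        return len(self.unique) + len(self.two_valued)

    @property
    def max_increment(self) -> int:
        return self.n_defined

    def encoded(self):
        """Position/value arrays for the numeric scoring kernels.

        Returns ``(upos, uval, tpos, tpref, talt)`` with 0-based positions.
        """
        up = sorted(self.unique)
        tp = sorted(self.two_valued)
        return (
            np.array([p - 1 for p in up], dtype=np.int64),
            np.array([_CODE[self.unique[p]] for p in up], dtype=np.uint8),
            np.array([p - 1 for p in tp], dtype=np.int64),
            np.array([_CODE[self.two_valued[p][0]] for p in tp], dtype=np.uint8),
            np.array([_CODE[self.two_valued[p][1]] for p in tp], dtype=np.uint8),
        )

    def relabel(self, mapping: Mapping[str, str]) -> "ConsensusSpec":
        """Apply a nucleotide permutation to every consensus value."""
        m = {_validate_base(k, "relabel"): _validate_base(v, "relabel") for k, v in mapping.items()}
        if sorted(m) != list(ALPHABET) or sorted(m.values()) != list(ALPHABET):
            raise ValueError("mapping must be a permutation of the alphabet")
        return ConsensusSpec(
            self.core_length,
            {p: m[b] for p, b in self.unique.items()},
            {p: (m[a], m[b]) for p, (a, b) in self.two_valued.items()},
        )


@dataclass(frozen=True)
class AlternativeConsensusSpec:
    """Consensus with two alternative domain structures sharing one fit set.

    The unique positions are required by both structures. The two-valued
    positions are partitioned into ``m1`` (structure I, the "rod") and
    ``m2`` (structure II, the "cloverleaf"); each maps a position to
    ``(structure value, alternative value)``. Either value fits, but a
    position only contributes +1 to the increment of *its own* structure,
    and only when it holds the structure value.
    """

    core_length: int
    unique: Mapping[int, str]
    m1: Mapping[int, tuple[str, str]]
    m2: Mapping[int, tuple[str, str]]

    def __post_init__(self):
        if set(self.m1) & set(self.m2):
            raise ValueError("m1 and m2 position sets overlap")
        base = ConsensusSpec(self.core_length, self.unique, {**self.m1, **self.m2})
        object.__setattr__(self, "unique", base.unique)
        object.__setattr__(self, "m1", {int(p): base.two_valued[int(p)] for p in self.m1})
        object.__setattr__(self, "m2", {int(p): base.two_valued[int(p)] for p in self.m2})

    @property
    def n_defined(self) -> int:
        return len(self.unique) + len(self.m1) + len(self.m2)

    @property
    def max_increment(self) -> int:
        """Best achievable increment: all uniques plus one full structure set."""
        return len(self.unique) + max(len(self.m1), len(self.m2))

    def as_simple(self) -> ConsensusSpec:
        """The underlying simple consensus (structure values as 'preferred')."""
        return ConsensusSpec(self.core_length, self.unique, {**self.m1, **self.m2})

    def encoded(self):
        """Arrays ``(upos, uval, m1pos, m1val, m1alt, m2pos, m2val, m2alt)``."""
        up = sorted(self.unique)

        def enc(group):
            ps = sorted(group)
            return (
                np.array([p - 1 for p in ps], dtype=np.int64),
                np.array([_CODE[group[p][0]] for p in ps], dtype=np.uint8),
                np.array([_CODE[group[p][1]] for p in ps], dtype=np.uint8),
            )

        m1pos, m1val, m1alt = enc(self.m1)
        m2pos, m2val, m2alt = enc(self.m2)
        return (
            np.array([p - 1 for p in up], dtype=np.int64),
            np.array([_CODE[self.unique[p]] for p in up], dtype=np.uint8),
            m1pos, m1val, m1alt,
            m2pos, m2val, m2alt,
        )

    def relabel(self, mapping: Mapping[str, str]) -> "AlternativeConsensusSpec":
        m = {_validate_base(k, "relabel"): _validate_base(v, "relabel") for k, v in mapping.items()}
        if sorted(m) != list(ALPHABET) or sorted(m.values()) != list(ALPHABET):
            raise ValueError("mapping must be a permutation of the alphabet")
        return AlternativeConsensusSpec(
            self.core_length,
            {p: m[b] for p, b in self.unique.items()},
            {p: (m[a], m[b]) for p, (a, b) in self.m1.items()},
            {p: (m[a], m[b]) for p, (a, b) in self.m2.items()},
        )


@dataclass(frozen=True)
class LayoutSpec:
    """Chromosome geometry: N segments of (core + window) nucleotides.

    ``delta`` is the fitness step per found domain and must exceed the
    largest possible gradual increment, so fitness levels of different
    epochs never overlap.
    """

    n_domains: int
    window: int
    core_length: int = 26
    delta: int = 100

    def __post_init__(self):
        if min(self.n_domains, self.window, self.core_length, self.delta) < 1:
            raise ValueError("all layout parameters must be positive integers")

    @property
    def segment_length(self) -> int:
        return self.core_length + self.window

    @property
    def total_length(self) -> int:
        """L = N * (core_length + window)."""
        return self.n_domains * self.segment_length

    def segment_bounds(self, i: int) -> tuple[int, int]:
        """0-based half-open bounds of segment ``i`` (0-based)."""
        if not (0 <= i < self.n_domains):
            raise ValueError(f"segment index {i} outside 0..{self.n_domains - 1}")
        return i * self.segment_length, (i + 1) * self.segment_length

    def validate_spec(self, spec) -> None:
        """Check a consensus is compatible: core length and level separation."""
        if spec.core_length != self.core_length:
            raise ValueError(
                f"consensus core length {spec.core_length} != layout core length {self.core_length}"
            )
        if self.delta <= spec.max_increment:
            raise ValueError(
                f"delta={self.delta} must exceed the maximum gradual increment "
                f"{spec.max_increment}, or fitness levels overlap"
            )

    @property
    def max_fitness_bound(self) -> int:
        """Upper bound N*(delta + core_length) on any total fitness."""
        return self.n_domains * (self.delta + self.core_length)
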