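"""Named consensus/layout fixtures for the benchmark problems.

Three consensus specifications, all on a 26-nt core derived from the
Sassanfar–Szostak ATP-aptamer motif, cover the benchmark family:

``ss_simple_4_10``
    Simple consensus: 4 unique positions (2, 6, 12, 25, all G) and 10
    two-valued positions (3-5, 7-11, 13, 24). The preferred/alternative
    letters at positions whose identity is not pinned by the worked
    scoring example (preferred at 4, 5, 7, 13; alternatives at 3, 8, 9,
    10, 24) are fixed arbitrarily, taken from the two-structure spec's
    value pairs where consistent. Search statistics are invariant under
    any consistent relabeling, so these choices are cosmetic.

``ss_alt``
    The same fit set organized as two alternative structures: the
    two-valued positions split into m1 = (3, 5, 7, 10, 11) with
    structure-I ("rod") values (A, G, G, A, C) and m2 = (4, 8, 9, 13, 24)
    with structure-II ("cloverleaf") values (U, C, C, A, C); the paired
    alternative value at each position never contributes to either
    structure's score. At position 11 the alternative is U, so that the
    canonical worked-example core (which carries U there) fits.

``six_plus_four``
    The reduced motif used for the search-efficiency sweeps: 6 unique
    positions (3, 5, 7, 10, 11, 12) and 4 two-valued positions
    (4, 8, 9, 13); letters fixed arbitrarily.

Default layouts put each core in a W = 220 window (segment length 246)
with a fitness step delta = 100.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consensus import AlternativeConsensusSpec, ConsensusSpec, LayoutSpec

__all__ = [
    "Fixture",
    "fixtures",
    "get_fixture",
    "EXAMPLE_CORE_SIMPLE",
    "EXAMPLE_CORE_ALT",
    "concretize",
    "worked_genome",
]

#: Worked scoring example for the simple consensus (increment 10).
EXAMPLE_CORE_SIMPLE = "NGGUGGGAACUGANNNNNNNNNNGGN"
#: Worked scoring example for the two-structure consensus (s1=6, s2=7).
EXAMPLE_CORE_ALT = "NGGUGGGCACUGANNNNNNNNNNGGN"

_UNIQUE_4 = {2: "G", 6: "G", 12: "G", 25: "G"}

# (preferred, alternative) pairs; see module docstring for which letters
# are pinned by the worked examples and which are arbitrary fixed choices.
_TWO_VALUED_10 = {
    3: ("G", "A"),
    4: ("A", "U"),
    5: ("A", "G"),
    7: ("A", "G"),
    8: ("A", "C"),
    9: ("A", "C"),
    10: ("C", "A"),
    11: ("U", "C"),
    13: ("C", "A"),
    24: ("G", "C"),
}

# (structure value, alternative) pairs; position 11's alternative is U,
# not A, so the canonical worked-example core fits the consensus.
_M1 = {3: ("A", "G"), 5: ("G", "A"), 7: ("G", "A"), 10: ("A", "C"), 11: ("C", "U")}
_M2 = {4: ("U", "A"), 8: ("C", "A"), 9: ("C", "A"), 13: ("A", "C"), 24: ("C", "G")}

_UNIQUE_6 = {3: "G", 5: "G", 7: "G", 10: "C", 11: "U", 12: "G"}
_TWO_VALUED_4 = {4: ("A", "U"), 8: ("A", "C"), 9: ("A", "C"), 13: ("C", "A")}


@dataclass(frozen=True)
class Fixture:
    name: str
    spec: ConsensusSpec | AlternativeConsensusSpec
    layout: LayoutSpec
    default_mode: str

    def with_layout(self, **kwargs) -> "Fixture":
        from dataclasses import replace
        return Fixture(self.name, self.spec, replace(self.layout, **kwargs), self.default_mode)


def fixtures() -> dict[str, Fixture]:
    """The named benchmark fixtures, freshly constructed."""
    return {
        "ss_simple_4_10": Fixture(
            "ss_simple_4_10",
            ConsensusSpec(26, _UNIQUE_4, _TWO_VALUED_10),
            LayoutSpec(n_domains=4, window=220),
            "simple",
        ),
        "ss_alt": Fixture(
            "ss_alt",
            AlternativeConsensusSpec(26, _UNIQUE_4, _M1, _M2),
            LayoutSpec(n_domains=4, window=220),
            "alternative",
        ),
        "six_plus_four": Fixture(
            "six_plus_four",
            ConsensusSpec(26, _UNIQUE_6, _TWO_VALUED_4),
            LayoutSpec(n_domains=8, window=220),
            "simple",
        ),
    }


def get_fixture(name: str, n_domains: int | None = None, window: int | None = None) -> Fixture:
    fx = fixtures()
    if name not in fx:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(fx)}")
    f = fx[name]
    over = {}
    if n_domains is not None:
        over["n_domains"] = n_domains
    if window is not None:
        over["window"] = window
    return f.with_layout(**over) if over else f


def concretize(core: str, fill: str = "A") -> str:
    """Replace the arbitrary (N/n) positions of a printed core by ``fill``."""
    return core.replace("N", fill).replace("n", fill)


def worked_genome(layout: LayoutSpec, core: str, fill: str = "A") -> str:
    """A chromosome whose first segment holds ``core`` at offset 0 and whose
    remaining positions are all ``fill`` (non-fitting for the fixtures here,
    whose consensuses all require non-``fill`` letters)."""
    c = concretize(core, fill)
    if len(c) != layout.core_length:
        raise ValueError(f"core length {len(c)} != layout core length {layout.core_length}")
    return c + fill * (layout.total_length - layout.core_length)
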