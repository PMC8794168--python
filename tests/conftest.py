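import numpy as np
import pytest

from biors import ConsensusSpec, AlternativeConsensusSpec, LayoutSpec, get_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_spec():
    """Small consensus (core 6: 2 unique + 2 two-valued) for fast searches."""
    return ConsensusSpec(6, {1: "G", 4: "C"}, {2: ("A", "U"), 5: ("G", "C")})


@pytest.fixture
def toy_layout():
    return LayoutSpec(n_domains=2, window=8, core_length=6, delta=100)


@pytest.fixture
def toy_alt_spec():
    """Small two-structure consensus: 1 unique, m1/m2 of two positions each."""
    return AlternativeConsensusSpec(
        6, {1: "G"},
        {2: ("A", "U"), 3: ("C", "G")},
        {4: ("U", "A"), 5: ("G", "C")},
    )


@pytest.fixture
def ss_simple():
    return get_fixture("ss_simple_4_10")


@pytest.fixture
def ss_alt():
    return get_fixture("ss_alt")


@pytest.fixture
def six_plus_four():
    return get_fixture("six_plus_four")
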