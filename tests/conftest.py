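import numpy as np
import pytest

from botryphylo.seqio import Alignment, PopulationMap


def random_alignment(rng, n, L, alphabet="ACGT"):
    seqs = ["".join(rng.choice(list(alphabet), size=L)) for _ in range(n)]
    return Alignment([f"s{i}" for i in range(n)], seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def two_group_map():
    """8 samples, 4 populations, 2 regions."""
    return PopulationMap(
        {f"s{i}": f"p{i // 2}" for i in range(8)},
        {"p0": "g0", "p1": "g0", "p2": "g1", "p3": "g1"},
    )


@pytest.fixture
def fixed_haplotype_alignment():
    """Each population fixed for a private haplotype."""
    return Alignment(
        [f"s{i}" for i in range(8)],
        ["AAAA", "AAAA", "AAAT", "AAAT", "AATT", "AATT", "ATTT", "ATTT"],
    )
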