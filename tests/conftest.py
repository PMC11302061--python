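import numpy as np
import pytest

from pmprofiler.io_formats import Lineage, SequenceRecord, TaxonomyMap
from pmprofiler.kmer_index import build_index


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_refs(rng: np.random.Generator, n: int, min_len: int = 50, max_len: int = 300):
    return [
        SequenceRecord(f"ref{i:03d}", random_seq(rng, int(rng.integers(min_len, max_len + 1))))
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def small_refs(rng):
    return random_refs(rng, 6, min_len=80, max_len=200)


@pytest.fixture
def small_index(small_refs):
    return build_index(small_refs, k=6)


def make_lineage(*names: str) -> Lineage:
    from pmprofiler.io_formats import RANK_PREFIXES

    return Lineage(tuple((RANK_PREFIXES[i], n) for i, n in enumerate(names)))


@pytest.fixture
def toy_taxonomy():
    """Six references across three species, two genera, one family."""
    linA = make_lineage("Bacteria", "P1", "C1", "O1", "F1", "G1", "SpA")
    linB = make_lineage("Bacteria", "P1", "C1", "O1", "F1", "G1", "SpB")
    linC = make_lineage("Bacteria", "P1", "C1", "O1", "F1", "G2", "SpC")
    return TaxonomyMap(
        {
            "ref000": linA,
            "ref001": linA,
            "ref002": linB,
            "ref003": linB,
            "ref004": linC,
            "ref005": linC,
        }
    )
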