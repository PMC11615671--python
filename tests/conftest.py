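import numpy as np
import pytest

from sncfrag.matcher import Alignment
from sncfrag.reference import NcRNARecord, ReferenceCatalog

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def brute_force_match(read: str, catalog: ReferenceCatalog,
                      len_min: int = 16, len_max: int = 32) -> set:
    """Independent oracle: scan every offset of every parent for the full read."""
    n = len(read)
    if not len_min <= n <= len_max or set(read) - set(BASES):
        return set()
    hits = set()
    for rec in catalog.records:
        for off in range(len(rec.sequence) - n + 1):
            if rec.sequence[off:off + n] == read:
                hits.add((rec.id, off))
    return hits


def make_alignment(parent_id: str, start: int, length: int = 20,
                   read_id: str = "r") -> Alignment:
    return Alignment(read_id=read_id, read_length=length, parent_id=parent_id,
                     start=start, end=start + length)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_catalog():
    """Three parents of two classes; t1 has an internal 4-periodic repeat."""
    return ReferenceCatalog(records=[
        NcRNARecord("t1", "tRNA", "ACGTACGTACGTACGTACGT"),
        NcRNARecord("t2", "tRNA", "TTTTCCCCGGGGAAAATTTTCCCC"),
        NcRNARecord("m1", "miRNA", "TGAGGTAGTAGGTTGTATAGTT"),
    ])


@pytest.fixture
def random_catalog(rng):
    recs = [
        NcRNARecord(f"p{i:02d}", "tRNA", random_seq(rng, int(rng.integers(40, 200))))
        for i in range(50)
    ]
    return ReferenceCatalog(records=recs)
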