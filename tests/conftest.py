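import pytest

from trnacif.dataset import AlignedTDNA, TDNADataset
from trnacif.sprinzl import SprinzlMap


@pytest.fixture
def map3():
    """Three columns, labels 1-3, with (1,3) paired."""
    return SprinzlMap(["1", "2", "3"], [("1", "3")])


@pytest.fixture
def map2():
    return SprinzlMap(["1", "2"])


def make_dataset(sprinzl, rows):
    """rows: (genome_id, gene_id, cls, seq) tuples."""
    return TDNADataset(sprinzl, [AlignedTDNA(*r) for r in rows])


@pytest.fixture
def two_class_ds(map2):
    """Two tDNAs 'AA' (F) and 'AC' (K)."""
    return make_dataset(map2, [("g1", "t1", "F", "AA"), ("g2", "t2", "K", "AC")])
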