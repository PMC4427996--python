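import numpy as np
import pytest

from paralogsites import Alignment, TaxonGrouping
from paralogsites.io import AMINO_ACIDS
from paralogsites.pipeline import make_benchmark_fixture

EIGHT_TAXA = (
    ("c1", ("A", "common")),
    ("c2", ("A", "common")),
    ("r1", ("A", "rare")),
    ("r2", ("A", "rare")),
    ("bc1", ("B", "common")),
    ("bc2", ("B", "common")),
    ("br1", ("B", "rare")),
    ("br2", ("B", "rare")),
)


@pytest.fixture(scope="session")
def eight_taxon_grouping() -> TaxonGrouping:
    return TaxonGrouping({t: g for t, g in EIGHT_TAXA})


def make_columns_alignment(columns: list[str], taxon_ids=None) -> Alignment:
    """Build an alignment from a list of column strings (one char per taxon)."""
    n_taxa = len(columns[0])
    if taxon_ids is None:
        taxon_ids = tuple(t for t, _ in EIGHT_TAXA[:n_taxa])
    rows = tuple("".join(col[i] for col in columns) for i in range(n_taxa))
    return Alignment(tuple(taxon_ids), rows)


def random_alignment(rng: np.random.Generator, n_taxa: int, n_columns: int) -> Alignment:
    aa = np.array(list(AMINO_ACIDS))
    rows = tuple("".join(aa[rng.integers(0, 20, n_columns)]) for _ in range(n_taxa))
    return Alignment(tuple(f"t{i}" for i in range(n_taxa)), rows)


@pytest.fixture(scope="session")
def benchmark_fixture():
    return make_benchmark_fixture()
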