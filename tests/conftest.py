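import numpy as np
import pytest

import mesotraject as mt


@pytest.fixture(scope="session")
def small_grn():
    return mt.syndata.simulate_grn(n_tf=10, density=0.15, seed=2)


@pytest.fixture(scope="session")
def cell_data(small_grn):
    """400 cells with 20 planted low-quality cells."""
    return mt.syndata.simulate_cells(small_grn, n_cells=400, n_lowq=20,
                                     seed=11)


@pytest.fixture(scope="session")
def clean_cells(small_grn):
    """300 cells, no planted QC failures."""
    return mt.syndata.simulate_cells(small_grn, n_cells=300, n_lowq=0,
                                     seed=12)


@pytest.fixture(scope="session")
def tracks():
    return mt.syndata.simulate_genome_tracks(seed=5)


def toy_matrix(counts, mito=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if mito is None:
        mito = np.zeros(n_genes, dtype=bool)
    return mt.CountMatrix(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        gene_ids=[f"g{i}" for i in range(n_genes)],
        mito_mask=np.asarray(mito, dtype=bool),
    )
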