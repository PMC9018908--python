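import numpy as np
import pytest
import scipy.sparse as sp

from dsbnorm import CountMatrix, SimConfig, generate


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size study conditions for unit tests (same noise structure)."""
    return SimConfig(seed=1, n_cells=400, n_empties=6000)


@pytest.fixture(scope="session")
def small_sim(small_config):
    cells, empties, truth = generate(small_config)
    return cells, empties, truth


@pytest.fixture
def tiny_counts():
    """3 proteins x 5 barcodes with a known sparsity pattern."""
    counts = np.array(
        [
            [1, 0, 2, 0, 3],
            [0, 4, 0, 0, 5],
            [6, 0, 0, 7, 0],
        ]
    )
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        protein_ids=np.array(["CD3", "CD19", "IgG1_isotype_ctrl"], dtype=object),
        barcode_ids=np.array([f"bc{i}" for i in range(5)], dtype=object),
    )
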