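import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from svzlineage.simulate import SimConfig, simulate_lineage_counts
from svzlineage.types import CountMatrix

SMALL_SIZES = {
    "B_quiescent": 80,
    "B_active": 40,
    "C": 60,
    "A_dividing": 40,
    "A_migrating": 60,
}


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, n_genes=600, stage_sizes=dict(SMALL_SIZES))


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_lineage_counts(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """Full default-configuration dataset, shared across recovery tests."""
    return simulate_lineage_counts(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_count_matrix(counts, cell_prefix="c", genes=None) -> CountMatrix:
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cells = pd.Index([f"{cell_prefix}{i}" for i in range(n_cells)], name="cell")
    if genes is None:
        genes = [f"g{j}" for j in range(n_genes)]
    return CountMatrix(
        sp.csr_matrix(counts),
        pd.DataFrame(index=cells),
        pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
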