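import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nvu_hetero.qc_io import ExpressionMatrix
from nvu_hetero.synthetic_data import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-structure simulated dataset shared across tests."""
    cfg = SimConfig(n_genes=500, n_cell_types=3, cells_per_type_per_group=60,
                    seed=42)
    matrix, meta, truth = simulate_counts(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture()
def tiny_matrix():
    """2-gene x 2-cell matrix: [[3,0],[0,1]]."""
    return ExpressionMatrix(
        sp.csr_matrix(np.array([[3, 0], [0, 1]])),
        np.array(["g1", "g2"], dtype=object),
        np.array(["c1", "c2"], dtype=object),
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        yield


def groups_series(meta: pd.DataFrame) -> pd.Series:
    return pd.Series(meta["group"].to_numpy(), index=meta["cell_id"])


def types_series(meta: pd.DataFrame) -> pd.Series:
    return pd.Series(meta["cell_type"].to_numpy(), index=meta["cell_id"])
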