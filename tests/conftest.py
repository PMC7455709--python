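import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import scsig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_dataset():
    """Small simulated matrix with a 5% planted signature-high subpopulation."""
    params = scsig.ScSimParams(
        n_cells=600, n_genes=800, planted_fraction=0.05, log_fc=1.5, seed=42
    )
    adata, truth = scsig.simulate_sc_counts(params)
    return adata, truth, params


@pytest.fixture(scope="session")
def null_dataset():
    """Signal-free simulated matrix (no planted effect)."""
    params = scsig.ScSimParams(
        n_cells=600, n_genes=800, planted_fraction=0.0, log_fc=0.0, seed=7
    )
    adata, _ = scsig.simulate_sc_counts(params)
    return adata


@pytest.fixture(scope="session")
def normalized_null(null_dataset):
    norm = scsig.log_normalize(null_dataset)
    rel = scsig.relative_expression(norm)
    bins = scsig.bin_genes_by_expression(norm, 25)
    return norm, rel, bins


@pytest.fixture()
def tiny_relative():
    """3-cell x 6-gene centered matrix with hand-readable values."""
    import anndata as ad

    X = np.array(
        [
            [1.0, 0.0, 2.0, -1.0, 0.5, 0.0],
            [0.0, 1.0, -2.0, 1.0, -0.5, 0.0],
            [-1.0, -1.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )
    X = X - X.mean(axis=0)  # center per gene
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(3)]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(6)]),
    )
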