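import numpy as np
import pandas as pd
import pytest

from modalfuse.bundle import make_bundle
from modalfuse.simulate import (
    bifurcation_topology,
    default_kinetics,
    simulate_kinetics,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_bundle(rng):
    """20 cells x 8 genes of random counts with metadata."""
    S = rng.poisson(5.0, (20, 8)).astype(float)
    U = rng.poisson(1.5, (20, 8)).astype(float)
    cell_meta = pd.DataFrame(
        {
            "batch": ["a"] * 10 + ["b"] * 10,
            "condition_label": (["control", "perturbed"] * 10)[:20],
            "cluster_label": ["c1"] * 7 + ["c2"] * 13,
        }
    )
    return make_bundle(S, U, cell_meta=cell_meta)


@pytest.fixture(scope="session")
def sim_bundle():
    """Simulated bifurcation used across modules (session-cached)."""
    topo = bifurcation_topology()
    params = default_kinetics(60, topo, seed=11)
    return simulate_kinetics(topo, params, n_cells=250, seed=11)


def brute_force_knn_adjacency(X, k):
    """Dense-distance k-NN oracle with lower-index tie-breaking."""
    import scipy.sparse as sp
    from scipy.spatial.distance import cdist

    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    n = X.shape[0]
    rows, cols = [], []
    for i in range(n):
        order = sorted(range(n), key=lambda j: (D[i, j], j))[:k]
        rows.extend([i] * k)
        cols.extend(order)
    return sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
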