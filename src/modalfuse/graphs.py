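"""Shared PCA / k-nearest-neighbor machinery.

Every integration strategy ultimately emits a k-NN graph (k=10 by default)
whose rows align with the input cell order; the helpers here centralize the
distance computation and the deterministic tie-break (ties in distance go
to the lower cell index).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .bundle import NeighborGraph


class DegenerateInputError(ValueError):
    """Raised when a matrix has no variance left to decompose."""


def pca_embed(X: np.ndarray, n_comps: int = 50, seed: int = 0) -> np.ndarray:
    """Top principal-component scores; uses all dimensions when d < n_comps."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise DegenerateInputError("PCA needs at least 2 observations")
    if not np.any(np.ptp(X, axis=0) > 0):
        raise DegenerateInputError("matrix is constant; PCA undefined")
    k = int(min(n_comps, d, n - 1))
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    return pca.fit_transform(X)


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    return cdist(X, X)


def knn_indices(X: np.ndarray, k: int, include_self: bool = False):
    """Indices and distances of the k nearest neighbors per row (dense, stable)."""
    n = X.shape[0]
    limit = n if include_self else n - 1
    if k > limit:
        raise ValueError(f"k={k} too large for n={n} (include_self={include_self})")
    D = pairwise_distances(X)
    if not include_self:
        np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    dist = np.take_along_axis(D, order, axis=1)
    return order, dist


def knn_graph(X: np.ndarray, k: int = 10, provenance: str = "") -> NeighborGraph:
    """Directed k-NN graph with unit connectivity weights."""
    n = X.shape[0]
    idx, _ = knn_indices(X, k)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    return NeighborGraph(adj, k=k, provenance=provenance)


def knn_graph_from_similarity(S: np.ndarray, k: int = 10, provenance: str = "") -> NeighborGraph:
    """Keep the k strongest off-diagonal similarities per row as edge weights."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} too large for n={n}")
    M = S.copy()
    np.fill_diagonal(M, -np.inf)
    order = np.argsort(-M, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    vals = np.take_along_axis(M, order, axis=1).ravel()
    vals = np.maximum(vals, 0.0)
    adj = sp.csr_matrix((vals, (rows, order.ravel())), shape=(n, n))
    return NeighborGraph(adj, k=k, provenance=provenance)


def symmetrize(graph: NeighborGraph) -> sp.csr_matrix:
    a = graph.adjacency
    return a.maximum(a.T).tocsr()


def row_normalize(W) -> np.ndarray:
    """D^{-1} W; all-zero rows stay zero."""
    W = np.asarray(W.todense() if sp.issparse(W) else W, dtype=float)
    d = W.sum(axis=1)
    out = np.zeros_like(W)
    nz = d > 0
    out[nz] = W[nz] / d[nz, None]
    return out
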