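"""k-NN moment smoothing and steady-state RNA-velocity estimation.

Moments are neighborhood averages of the spliced/unspliced layers over a
size-k Euclidean neighborhood (the cell plus its k-1 nearest neighbors) in
PCA space of the spliced layer; they denoise the per-gene phase space
before fitting.  Velocity is then estimated per gene under the steady-state
assumption: the extreme quantiles of the phase space are taken to sit on
the steady-state line u = gamma' * s, the ratio gamma' is fitted by
zero-intercept least squares, and v = Mu - gamma' * Ms measures each
cell's displacement off that line (positive while a gene is being induced,
negative during repression).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .bundle import ModalityBundle
from .graphs import DegenerateInputError, knn_indices, pca_embed


def compute_moments(bundle: ModalityBundle, k: int = 10, n_pcs: int = 50) -> ModalityBundle:
    """Add ``moments_spliced`` / ``moments_unspliced`` layers (k-NN means).

    The neighborhood of cell i is {i} plus its k-1 nearest neighbors by
    Euclidean distance in the top ``n_pcs`` principal components of the
    spliced layer; the averaging operator is row-stochastic by construction.
    """
    n = bundle.n_cells
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    S = bundle.layers["spliced"]
    U = bundle.layers["unspliced"]
    if k == 1:
        idx = np.arange(n)[:, None]
    else:
        try:
            Z = pca_embed(S, n_comps=n_pcs)
        except DegenerateInputError:
            Z = np.zeros((n, 1))  # all cells identical: any neighborhood works
        nbrs, _ = knn_indices(Z, k - 1)
        idx = np.hstack([np.arange(n)[:, None], nbrs])
    out = bundle.copy()
    out.layers["moments_spliced"] = S[idx].mean(axis=1)
    out.layers["moments_unspliced"] = U[idx].mean(axis=1)
    return out


def estimate_velocity_steady_state(
    Ms: np.ndarray, Mu: np.ndarray, quantile: float = 0.95
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-gene steady-state ratio and velocity layer ``V = Mu - ratio * Ms``.

    The ratio is the zero-intercept least-squares slope of Mu on Ms over
    the cells in the upper ``quantile`` and lower ``1 - quantile`` tails of
    Ms for that gene.  Genes with all-zero Ms get ratio 0 (so V = Mu there)
    and are left for the caller to flag.

    Returns ``(V, ratio)``.
    """
    Ms = np.asarray(Ms, dtype=float)
    Mu = np.asarray(Mu, dtype=float)
    if Ms.shape != Mu.shape:
        raise ValueError("Ms and Mu must share a shape")
    if not 0.5 < quantile < 1.0:
        raise ValueError("quantile must be in (0.5, 1)")
    n, d = Ms.shape
    ratio = np.zeros(d)
    hi = np.quantile(Ms, quantile, axis=0)
    lo = np.quantile(Ms, 1.0 - quantile, axis=0)
    for g in range(d):
        mask = (Ms[:, g] >= hi[g]) | (Ms[:, g] <= lo[g])
        s, u = Ms[mask, g], Mu[mask, g]
        denom = (s * s).sum()
        ratio[g] = (u * s).sum() / denom if denom > 0 else 0.0
    V = Mu - ratio[None, :] * Ms
    return V, ratio


def add_velocity(bundle: ModalityBundle, k: int = 10, n_pcs: int = 50, quantile: float = 0.95) -> ModalityBundle:
    """Convenience pipeline: moments then steady-state velocity layer."""
    out = bundle if "moments_spliced" in bundle.layers else compute_moments(bundle, k=k, n_pcs=n_pcs)
    V, ratio = estimate_velocity_steady_state(
        out.layers["moments_spliced"], out.layers["moments_unspliced"], quantile=quantile
    )
    out = out.copy()
    out.layers["velocity"] = V
    out.uns["steady_state_ratio"] = ratio
    return out
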