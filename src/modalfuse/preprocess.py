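"""Quality control, normalization, HVG selection, and geometric sketching.

Filtering and normalization treat spliced and unspliced counts jointly: a
gene must be expressed (S + U) in enough cells and carry enough total
counts across both layers, and one size factor per cell rescales both
layers so the u/s phase-space relationship is preserved.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr

from .bundle import BundleError, ModalityBundle


def filter_genes_cells(
    bundle: ModalityBundle,
    min_cells: int = 5,
    min_counts: int = 5,
    max_mito_frac: float = 0.2,
    mito_prefix: str = "mt-",
) -> ModalityBundle:
    """QC-filter genes and cells on the joint spliced+unspliced counts.

    A gene is kept iff it is expressed (S+U > 0) in at least ``min_cells``
    cells and its total S+U count is at least ``min_counts``.  A cell is
    kept iff the fraction of its spliced counts on mitochondrial genes
    (gene_id starting with ``mito_prefix``, case-insensitive) is below
    ``max_mito_frac``.  Both layers are subset identically.
    """
    S = bundle.layers["spliced"]
    U = bundle.layers["unspliced"]
    mito = np.array(
        [str(g).lower().startswith(mito_prefix.lower()) for g in bundle.gene_ids]
    )
    tot_s = S.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(tot_s > 0, S[:, mito].sum(axis=1) / np.maximum(tot_s, 1e-300), 0.0)
    keep_cells = mito_frac < max_mito_frac

    T = (S + U)[keep_cells]
    expressed_in = (T > 0).sum(axis=0)
    total = T.sum(axis=0)
    keep_genes = (expressed_in >= min_cells) & (total >= min_counts)
    if not keep_genes.any():
        raise BundleError(
            "all genes removed by QC; relax min_cells/min_counts "
            f"(currently {min_cells}/{min_counts})"
        )
    return bundle.subset(cells=np.where(keep_cells)[0], genes=np.where(keep_genes)[0])


def _pooled_size_factors(T: np.ndarray, pool_size: int = 20) -> np.ndarray:
    """Simplified pooling normalization: overlapping ring pools of cells,
    pool-level factors against a mean pseudo-cell, deconvolved to per-cell
    factors by least squares."""
    n = T.shape[0]
    pool_size = min(pool_size, n)
    order = np.argsort(T.sum(axis=1), kind="stable")
    ref = T.mean(axis=0)
    ok = ref > 0
    rows, cols, b = [], [], []
    for p in range(n):
        members = order[(np.arange(p, p + pool_size)) % n]
        pooled = T[members].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = pooled[ok] / ref[ok]
        b.append(np.median(ratio))
        rows.extend([p] * pool_size)
        cols.extend(members.tolist())
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    sol = lsqr(A, np.asarray(b), damp=1e-6)[0]
    sol = np.maximum(sol, 1e-8)
    return sol / sol.mean()


def normalize(
    bundle: ModalityBundle,
    method: str = "library_size",
    batch_rescale: bool = False,
) -> Tuple[ModalityBundle, np.ndarray]:
    """Depth-normalize both layers with one size factor per cell.

    Size factors are computed on the joint S+U counts (``library_size``:
    proportional to total counts; ``pooled``: deconvolved from overlapping
    cell pools) and scaled to mean 1.  With ``batch_rescale``, factors are
    first centered within batch and then multiplied by the per-batch median
    ratio of per-gene average counts against the shallowest batch, so
    deeper batches are downsampled toward it.
    """
    S = bundle.layers["spliced"]
    U = bundle.layers["unspliced"]
    T = S + U
    totals = T.sum(axis=1)
    if np.any(totals <= 0):
        raise BundleError("cells with zero total counts present; run QC filtering first")
    if method == "library_size":
        sf = totals / totals.mean()
    elif method == "pooled":
        sf = _pooled_size_factors(T)
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    if batch_rescale:
        bundle.require_columns("batch")
        batch = bundle.cell_meta["batch"].to_numpy()
        ubatch = list(pd.unique(batch))
        med_depth = {b: np.median(totals[batch == b]) for b in ubatch}
        ref = min(ubatch, key=lambda b: med_depth[b])
        avg = {b: T[batch == b].mean(axis=0) for b in ubatch}
        ok = avg[ref] > 0
        for b in ubatch:
            mask = batch == b
            sf[mask] = sf[mask] / sf[mask].mean()  # center within batch
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.median(avg[b][ok & (avg[b] > 0)] / avg[ref][ok & (avg[b] > 0)])
            sf[mask] *= r if np.isfinite(r) and r > 0 else 1.0

    out = bundle.copy()
    for layer in ("spliced", "unspliced"):
        out.layers[layer] = out.layers[layer] / sf[:, None]
    out.uns["size_factors"] = sf
    return out, sf


def select_hvg(
    bundle: ModalityBundle,
    min_mean: float = 0.012,
    min_disp: float = 0.25,
    max_mean: float = 5.0,
    n_bins: int = 20,
) -> np.ndarray:
    """Flag highly variable genes by binned normalized dispersion.

    On the log1p-transformed normalized spliced layer, per-gene dispersion
    (variance/mean) is z-scored within ``n_bins`` equal-count bins of the
    mean; a gene is flagged iff ``min_mean < mean < max_mean`` and its
    normalized dispersion is at least ``min_disp``.  The mask is written to
    ``gene_meta['highly_variable']`` and returned.
    """
    X = np.log1p(bundle.layers["spliced"])
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    n_bins = min(n_bins, max(1, len(np.unique(mean))))
    try:
        bins = pd.qcut(mean, q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(len(mean), dtype=int)
    bins = np.asarray(bins)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        mu, sd = disp[m].mean(), disp[m].std(ddof=1) if m.sum() > 1 else 0.0
        z[m] = (disp[m] - mu) / sd if sd and np.isfinite(sd) and sd > 0 else 0.0

    mask = (mean > min_mean) & (mean < max_mean) & (z >= min_disp)
    bundle.gene_meta["highly_variable"] = mask
    return mask


def geometric_sketch(
    matrix: np.ndarray,
    fraction: float = 0.2,
    seed: int = 0,
    n_pcs: int = 10,
) -> np.ndarray:
    """Geometry-preserving subsample via an equal-volume hypercube covering.

    The data are projected to ``n_pcs`` principal components and scaled to
    the unit box; the grid resolution is chosen by binary search so the
    number of occupied hypercubes approximately matches the target sketch
    size.  Occupied boxes are then sampled round-robin, one random cell per
    box per round, until ``ceil(fraction * n)`` cells are drawn.  Because
    every occupied box is visited each round, rare cell populations are
    sampled at least at their share of occupied space.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    target = int(np.ceil(fraction * n))
    if target >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)

    from .graphs import pca_embed

    Z = pca_embed(X, n_comps=min(n_pcs, X.shape[1]), seed=seed)
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Zu = (Z - lo) / span

    def occupied(g: int) -> dict:
        keys = np.minimum((Zu * g).astype(int), g - 1)
        boxes: dict = {}
        for i, key in enumerate(map(tuple, keys)):
            boxes.setdefault(key, []).append(i)
        return boxes

    g_lo, g_hi = 1, max(2, n)
    while g_lo < g_hi:  # smallest resolution with >= target occupied boxes
        mid = (g_lo + g_hi) // 2
        if len(occupied(mid)) >= target:
            g_hi = mid
        else:
            g_lo = mid + 1
    boxes = occupied(g_lo)

    box_list = list(boxes.values())
    rng.shuffle(box_list)
    for members in box_list:
        rng.shuffle(members)
    chosen: list = []
    round_idx = 0
    while len(chosen) < target:
        progressed = False
        for members in box_list:
            if round_idx < len(members):
                chosen.append(members[round_idx])
                progressed = True
                if len(chosen) == target:
                    break
        round_idx += 1
        if not progressed:  # pragma: no cover - cannot happen while target < n
            warnings.warn("sketch exhausted all cells early")
            break
    return np.sort(np.asarray(chosen[:target]))
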