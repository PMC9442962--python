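"""Trajectory prediction from integrated graphs and reference-based scoring.

A predicted trajectory consists of (1) a milestone network whose edges
connect annotated cell populations with a connectivity weight in [0, 1]
derived from the integrated k-NN graph, and (2) per-cell positions along
milestone edges derived from diffusion pseudotime.  Predictions are scored
against a reference trajectory by

* ``C_corr`` -- Spearman correlation of geodesic cell-cell distances on the
  two trajectory networks,
* ``F_corr`` -- Pearson correlation of per-gene feature-importance scores
  from random forests regressing expression on cell-to-milestone geodesic
  distances,

combined into ``TI_corr``, their harmonic mean (negatives clipped to 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path
from scipy.stats import spearmanr

from .bundle import ModalityBundle, NeighborGraph
from .graphs import symmetrize


@dataclass
class TrajectoryGraph:
    """Milestone network plus per-cell positions along its edges."""

    milestones: List[str]
    edges: List[Tuple[str, str]]
    connectivity: List[float]
    root: str
    cell_positions: pd.DataFrame  # columns: source, target, fraction
    pseudotime: Optional[np.ndarray] = None
    flags: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.connectivity) != len(self.edges):
            raise ValueError("connectivity must align with edges")
        if any(not 0 <= c <= 1 for c in self.connectivity):
            raise ValueError("connectivity values must lie in [0, 1]")
        fr = self.cell_positions["fraction"].to_numpy()
        if fr.size and (fr.min() < -1e-9 or fr.max() > 1 + 1e-9):
            raise ValueError("cell fractions must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.cell_positions)

    # -- geodesics --------------------------------------------------------
    def _milestone_distances(self) -> np.ndarray:
        m = len(self.milestones)
        idx = {name: i for i, name in enumerate(self.milestones)}
        rows, cols = [], []
        for a, b in self.edges:
            if a != b:
                rows.append(idx[a])
                cols.append(idx[b])
        adj = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(m, m)
        )
        D = shortest_path(adj, directed=False, unweighted=True)
        cap = float(m)  # disconnected milestones sit at a finite cap
        D[~np.isfinite(D)] = cap
        return D

    def _position_arrays(self):
        idx = {name: i for i, name in enumerate(self.milestones)}
        a = self.cell_positions["source"].map(idx).to_numpy()
        b = self.cell_positions["target"].map(idx).to_numpy()
        f = self.cell_positions["fraction"].to_numpy(dtype=float)
        self_loop = a == b
        off_a = np.where(self_loop, 0.0, f)
        off_b = np.where(self_loop, 0.0, 1.0 - f)
        return a, b, off_a, off_b

    def cell_to_milestone_distances(self) -> np.ndarray:
        """(n_cells, n_milestones) geodesic distances with edge offsets."""
        D = self._milestone_distances()
        a, b, off_a, off_b = self._position_arrays()
        return np.minimum(off_a[:, None] + D[a], off_b[:, None] + D[b])

    def cell_pair_distances(self) -> np.ndarray:
        """All-pairs geodesic cell distances over the milestone network."""
        D = self._milestone_distances()
        a, b, off_a, off_b = self._position_arrays()
        cand = np.minimum.reduce(
            [
                off_a[:, None] + D[np.ix_(a, a)] + off_a[None, :],
                off_a[:, None] + D[np.ix_(a, b)] + off_b[None, :],
                off_b[:, None] + D[np.ix_(b, a)] + off_a[None, :],
                off_b[:, None] + D[np.ix_(b, b)] + off_b[None, :],
            ]
        )
        f = self.cell_positions["fraction"].to_numpy(dtype=float)
        same = (a[:, None] == a[None, :]) & (b[:, None] == b[None, :])
        cand = np.where(same, np.minimum(cand, np.abs(f[:, None] - f[None, :])), cand)
        rev = (a[:, None] == b[None, :]) & (b[:, None] == a[None, :]) & (a != b)[:, None]
        cand = np.where(rev, np.minimum(cand, np.abs(f[:, None] - (1.0 - f[None, :]))), cand)
        np.fill_diagonal(cand, 0.0)
        return cand


def reference_from_bundle(bundle: ModalityBundle) -> TrajectoryGraph:
    """Ground-truth trajectory of a simulated bundle (connectivity 1 edges)."""
    topo = bundle.uns["topology"]
    t = bundle.cell_meta["latent_time"].to_numpy(dtype=float)
    span = t.max() - t.min()
    pt = (t - t.min()) / span if span > 0 else np.zeros_like(t)
    positions = bundle.cell_meta[["edge_source", "edge_target", "edge_fraction"]].copy()
    positions.columns = ["source", "target", "fraction"]
    return TrajectoryGraph(
        milestones=list(topo.milestones),
        edges=list(topo.edges),
        connectivity=[1.0] * len(topo.edges),
        root=topo.root,
        cell_positions=positions.reset_index(drop=True),
        pseudotime=pt,
    )


# ---------------------------------------------------------------------------
# trajectory prediction
# ---------------------------------------------------------------------------

def cluster_connectivity(graph: NeighborGraph, cluster_labels: Sequence) -> Dict[Tuple[str, str], float]:
    """PAGA-like connectivity between annotated clusters.

    The observed inter-cluster edge mass is divided by its expectation
    under uniform random placement of the same total edge mass over all
    cell pairs, capped at 1.  Symmetric by construction.
    """
    labels = np.asarray(cluster_labels)
    A = symmetrize(graph)
    n = A.shape[0]
    total_pairs = n * (n - 1) / 2.0
    T = A.sum() / 2.0
    out: Dict[Tuple[str, str], float] = {}
    uniq = list(pd.unique(labels))
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            ma, mb = labels == a, labels == b
            obs = A[np.ix_(np.where(ma)[0], np.where(mb)[0])].sum()
            exp = T * (ma.sum() * mb.sum()) / total_pairs
            out[(a, b)] = min(1.0, obs / exp) if exp > 0 else 0.0
    return out


def diffusion_pseudotime(
    graph: NeighborGraph, root_cell: int, n_dcs: int = 20, density_normalize: bool = True
) -> np.ndarray:
    """Diffusion-pseudotime from a root cell, min-max scaled to [0, 1].

    The symmetrized graph's random-walk operator (after anisotropic
    density normalization, which recovers geometry independent of sampling
    density) is eigendecomposed via its symmetric conjugate; pseudotime is
    the diffusion distance to the root accumulated over the top ``n_dcs``
    nontrivial components with weights lambda/(1-lambda).
    """
    W = np.asarray(symmetrize(graph).todense(), dtype=float)
    n = W.shape[0]
    if density_normalize:
        q = np.maximum(W.sum(axis=1), 1e-12)
        W = W / (q[:, None] * q[None, :])
    d = W.sum(axis=1)
    inv_sqrt = np.zeros(n)
    nz = d > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
    M = W * inv_sqrt[:, None] * inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    nontrivial = vals < 1.0 - 1e-9  # drop per-component stationary modes
    vals, vecs = vals[nontrivial], vecs[:, nontrivial]
    ncomp = min(n_dcs, vals.size)
    lam = np.clip(vals[:ncomp], -1.0 + 1e-12, 1.0 - 1e-12)
    psi = vecs[:, :ncomp] * inv_sqrt[:, None]
    w = lam / (1.0 - lam)
    diff = (psi - psi[root_cell]) * w[None, :]
    dist = np.sqrt((diff ** 2).sum(axis=1))
    span = dist.max() - dist.min()
    return (dist - dist.min()) / span if span > 0 else np.zeros(n)


def _minmax(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    return (x - x.min()) / span if span > 0 else np.full_like(x, 0.5)


def predict_trajectory(
    graph: NeighborGraph,
    cluster_labels: Sequence,
    root_cluster: str,
    n_roots: int = 10,
    connectivity_threshold: float = 0.05,
    seed: int = 0,
    n_dcs: int = 20,
) -> List[TrajectoryGraph]:
    """Infer one trajectory per random root cell from the root cluster.

    Cluster-graph edges above the connectivity threshold are oriented away
    from the root by ascending median cluster pseudotime; each cell is
    placed on the edge entering its cluster (cells of the root cluster on
    its strongest outgoing edge) with a fraction given by min-max
    normalized pseudotime within the cluster.
    """
    labels = np.asarray(cluster_labels)
    if root_cluster not in labels:
        raise ValueError(f"root cluster {root_cluster!r} absent from labels")
    conn = cluster_connectivity(graph, labels)
    kept = {pair: c for pair, c in conn.items() if c > connectivity_threshold}
    milestones = list(pd.unique(labels))
    rng = np.random.default_rng(seed)
    candidates = np.where(labels == root_cluster)[0]
    roots = rng.choice(candidates, size=n_roots, replace=len(candidates) < n_roots)

    out: List[TrajectoryGraph] = []
    for root in roots:
        pt = diffusion_pseudotime(graph, int(root), n_dcs=n_dcs)
        med = {c: float(np.median(pt[labels == c])) for c in milestones}
        edges, weights = [], []
        for (a, b), c in kept.items():
            a2, b2 = (a, b) if med[a] <= med[b] else (b, a)
            edges.append((a2, b2))
            weights.append(c)

        incoming: Dict[str, Tuple[str, float]] = {}
        outgoing: Dict[str, Tuple[str, float]] = {}
        for (a, b), c in zip(edges, weights):
            if c > incoming.get(b, ("", -1.0))[1]:
                incoming[b] = (a, c)
            if c > outgoing.get(a, ("", -1.0))[1]:
                outgoing[a] = (b, c)

        src = np.empty(len(labels), dtype=object)
        tgt = np.empty(len(labels), dtype=object)
        frac = np.zeros(len(labels))
        isolated = []
        for c in milestones:
            m = labels == c
            local = _minmax(pt[m])
            if c in incoming:
                src[m], tgt[m], frac[m] = incoming[c][0], c, local
            elif c in outgoing:
                src[m], tgt[m], frac[m] = c, outgoing[c][0], 0.5 * local
            else:
                isolated.append(c)
                src[m], tgt[m], frac[m] = c, c, 0.0
        if isolated:
            warnings.warn(
                f"isolated milestones without surviving edges: {isolated}",
                stacklevel=2,
            )
        positions = pd.DataFrame({"source": src, "target": tgt, "fraction": frac})
        out.append(
            TrajectoryGraph(
                milestones=milestones,
                edges=edges,
                connectivity=weights,
                root=root_cluster,
                cell_positions=positions,
                pseudotime=pt,
                flags={"root_cell": int(root), "isolated": isolated},
            )
        )
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def cell_distance_correlation(
    ref: TrajectoryGraph,
    pred: TrajectoryGraph,
    n_pairs_sample: Optional[int] = None,
    seed: int = 0,
) -> float:
    """Spearman correlation of geodesic cell distances (C_corr)."""
    if ref.n_cells != pred.n_cells:
        raise ValueError("trajectories must cover the same cells")
    iu = np.triu_indices(ref.n_cells, 1)
    dr = ref.cell_pair_distances()[iu]
    dp = pred.cell_pair_distances()[iu]
    if n_pairs_sample is not None and n_pairs_sample < dr.size:
        rng = np.random.default_rng(seed)
        pick = rng.choice(dr.size, size=n_pairs_sample, replace=False)
        dr, dp = dr[pick], dp[pick]
    if np.ptp(dr) == 0 or np.ptp(dp) == 0:
        return 0.0
    rho = spearmanr(dr, dp).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def _forest_scores(features: np.ndarray, expression: np.ndarray, n_trees: int, seed: int) -> np.ndarray:
    from sklearn.ensemble import RandomForestRegressor

    scores = np.zeros(expression.shape[1])
    for g in range(expression.shape[1]):
        y = expression[:, g]
        if np.ptp(y) == 0:
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees, oob_score=True, bootstrap=True,
            random_state=seed, n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(features, y)
        scores[g] = max(0.0, float(rf.oob_score_))
    return scores


def feature_importance_correlation(
    ref: TrajectoryGraph,
    pred: TrajectoryGraph,
    expression: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    ref_scores: Optional[np.ndarray] = None,
) -> float:
    """Pearson correlation of per-gene forest scores (F_corr).

    Each gene's expression is regressed on the cell-to-milestone geodesic
    distances of a trajectory with a random forest; the per-gene score is
    the out-of-bag R^2 floored at 0, and F_corr correlates the reference
    and predicted score vectors.  ``ref_scores`` allows reusing the
    reference side across multiple predictions.
    """
    expression = np.asarray(expression, dtype=float)
    if ref_scores is None:
        ref_scores = _forest_scores(ref.cell_to_milestone_distances(), expression, n_trees, seed)
    pred_scores = _forest_scores(pred.cell_to_milestone_distances(), expression, n_trees, seed)
    if np.ptp(ref_scores) == 0 or np.ptp(pred_scores) == 0:
        return 0.0
    return float(np.corrcoef(ref_scores, pred_scores)[0, 1])


def reference_feature_scores(ref: TrajectoryGraph, expression: np.ndarray, n_trees: int = 100, seed: int = 0) -> np.ndarray:
    return _forest_scores(ref.cell_to_milestone_distances(), np.asarray(expression, float), n_trees, seed)


def ti_score(C_corr: float, F_corr: float) -> float:
    """Harmonic mean of the two correlation metrics; negatives clip to 0."""
    c = max(0.0, float(C_corr))
    f = max(0.0, float(F_corr))
    if c + f == 0:
        return 0.0
    return 2.0 * c * f / (c + f)


@dataclass
class TIScore:
    C_corr: float
    F_corr: float
    TI_corr: float


def score_trajectory(
    ref: TrajectoryGraph,
    pred: TrajectoryGraph,
    expression: np.ndarray,
    n_trees: int = 100,
    n_pairs_sample: Optional[int] = None,
    seed: int = 0,
    ref_scores: Optional[np.ndarray] = None,
) -> TIScore:
    c = cell_distance_correlation(ref, pred, n_pairs_sample=n_pairs_sample, seed=seed)
    f = feature_importance_correlation(
        ref, pred, expression, n_trees=n_trees, seed=seed, ref_scores=ref_scores
    )
    return TIScore(C_corr=c, F_corr=f, TI_corr=ti_score(c, f))
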