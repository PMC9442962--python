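"""Ten strategies for integrating two expression modalities over one set
of cells.

Each strategy consumes two cells x genes matrices (typically normalized
log spliced/unspliced layers, or spliced moments plus RNA velocity) and
emits a k-NN :class:`~modalfuse.bundle.NeighborGraph` (k=10 by default)
aligned with the input cell order, plus -- where the method defines one --
an :class:`~modalfuse.bundle.Embedding` and/or a row-stochastic
:class:`~modalfuse.bundle.TransitionMatrix`.

The strategies span the main families of multi-modal integration:
feature-level merging (concatenation, sum), Markov-chain blending of
expression and velocity transition operators, subspace alignment
(principal vectors), graph fusion by cross-diffusion (SNF), joint spectral
embeddings on the Grassmann manifold, alternating diffusion operators,
shared-factor matrix decomposition, and per-cell weighted nearest
neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
import scipy.linalg
from numpy.linalg import matrix_power

from .bundle import Embedding, NeighborGraph, TransitionMatrix
from .graphs import (
    DegenerateInputError,
    knn_graph,
    knn_graph_from_similarity,
    knn_indices,
    pairwise_distances,
    pca_embed,
    row_normalize,
)


@dataclass
class IntegrationResult:
    graph: NeighborGraph
    embedding: Optional[Embedding] = None
    transition: Optional[TransitionMatrix] = None
    extras: Dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# baselines: unintegrated / concatenation / sum
# ---------------------------------------------------------------------------

def integrate_unintegrated(X: np.ndarray, k: int = 10, n_pcs: int = 50, seed: int = 0) -> IntegrationResult:
    """PCA + k-NN on a single modality (the conventional spliced-only view)."""
    Z = pca_embed(X, n_comps=n_pcs, seed=seed)
    return IntegrationResult(
        graph=knn_graph(Z, k=k, provenance="unintegrated"),
        embedding=Embedding(Z, method="unintegrated"),
    )


def integrate_concat(X1: np.ndarray, X2: np.ndarray, k: int = 10, n_pcs: int = 50, seed: int = 0) -> IntegrationResult:
    """Horizontal concatenation [X1 || X2] -> PCA -> k-NN."""
    X = np.hstack([np.asarray(X1, float), np.asarray(X2, float)])
    Z = pca_embed(X, n_comps=n_pcs, seed=seed)
    return IntegrationResult(
        graph=knn_graph(Z, k=k, provenance="concat"),
        embedding=Embedding(Z, method="concat"),
    )


def integrate_sum(X1: np.ndarray, X2: np.ndarray, k: int = 10, n_pcs: int = 50, seed: int = 0) -> IntegrationResult:
    """Element-wise sum X1 + X2 -> PCA -> k-NN."""
    X = np.asarray(X1, float) + np.asarray(X2, float)
    try:
        Z = pca_embed(X, n_comps=n_pcs, seed=seed)
    except DegenerateInputError as exc:
        raise DegenerateInputError(f"summed matrix is degenerate: {exc}") from exc
    return IntegrationResult(
        graph=knn_graph(Z, k=k, provenance="sum"),
        embedding=Embedding(Z, method="sum"),
    )


# ---------------------------------------------------------------------------
# velocity-aware Markov blending
# ---------------------------------------------------------------------------

def expression_transition(graph: NeighborGraph) -> TransitionMatrix:
    """Uniform random-walk operator over the expression k-NN graph."""
    P = row_normalize(graph.adjacency)
    empty = P.sum(axis=1) == 0
    if empty.any():  # isolated cells stay put
        P[empty, empty] = 1.0
    return TransitionMatrix(P, kind="expression")


def velocity_transition(
    graph: NeighborGraph,
    Ms: np.ndarray,
    V: np.ndarray,
    scheme: str = "cosine",
) -> TransitionMatrix:
    """Transition probabilities biased by velocity/displacement agreement.

    For each cell i and neighbor j, the velocity vector V[i] is compared
    with the expression displacement Ms[j] - Ms[i] under the chosen
    similarity (``cosine``, ``correlation``, or ``dot``); the row is turned
    into probabilities with an exponential kernel.  Cells with zero
    velocity fall back to a uniform distribution over their neighbors.
    """
    Ms = np.asarray(Ms, float)
    V = np.asarray(V, float)
    if Ms.shape != V.shape:
        raise ValueError("Ms and V must be aligned")
    n = graph.n_cells
    adj = graph.adjacency
    P = np.zeros((n, n))
    for i in range(n):
        nbrs = adj.indices[adj.indptr[i]:adj.indptr[i + 1]]
        if nbrs.size == 0:
            P[i, i] = 1.0
            continue
        v = V[i]
        delta = Ms[nbrs] - Ms[i]
        vn = np.linalg.norm(v)
        if vn == 0:
            P[i, nbrs] = 1.0 / nbrs.size
            continue
        if scheme == "cosine":
            dn = np.linalg.norm(delta, axis=1)
            score = np.where(dn > 0, delta @ v / (np.maximum(dn, 1e-300) * vn), 0.0)
        elif scheme == "correlation":
            vc = v - v.mean()
            dc = delta - delta.mean(axis=1, keepdims=True)
            num = dc @ vc
            den = np.linalg.norm(dc, axis=1) * np.linalg.norm(vc)
            score = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        elif scheme == "dot":
            score = delta @ v
            sd = score.std()
            if sd > 0:
                score = score / sd
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        w = np.exp(score - score.max())
        P[i, nbrs] = w / w.sum()
    return TransitionMatrix(P, kind="velocity")


def integrate_cellrank(
    P_s: TransitionMatrix,
    P_v: TransitionMatrix,
    lam: float,
    k: int = 10,
) -> IntegrationResult:
    """Convex combination P = lam * P_v + (1 - lam) * P_s of the velocity
    and expression Markov operators; the output graph keeps the k strongest
    entries per row of the symmetrized combination."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    if P_s.P.shape != P_v.P.shape:
        raise ValueError("transition matrices must share a shape")
    P = lam * P_v.P + (1.0 - lam) * P_s.P
    fused = TransitionMatrix(P, kind="fused")
    sym = (P + P.T) / 2.0
    graph = knn_graph_from_similarity(sym, k=k, provenance="cellrank").symmetrized()
    return IntegrationResult(graph=graph, transition=fused)


# ---------------------------------------------------------------------------
# similarity network fusion
# ---------------------------------------------------------------------------

def _snf_affinity(X: np.ndarray, k: int, mu: float) -> np.ndarray:
    D = pairwise_distances(X)
    n = D.shape[0]
    Dn = D.copy()
    np.fill_diagonal(Dn, np.inf)
    knn_d = np.sort(Dn, axis=1)[:, :k]
    local = knn_d.mean(axis=1)
    eps = (local[:, None] + local[None, :] + D) / 3.0
    W = np.exp(-(D ** 2) / np.maximum(mu * eps, 1e-300))
    return W


def _snf_status(W: np.ndarray) -> np.ndarray:
    """Full-kernel status matrix: off-diagonal mass halved, 1/2 self-weight."""
    P = np.zeros_like(W)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rows = off.sum(axis=1)
    nz = rows > 0
    P[nz] = off[nz] / (2.0 * rows[nz, None])
    np.fill_diagonal(P, 0.5)
    return P


def _snf_local(W: np.ndarray, k: int) -> np.ndarray:
    """k-NN-truncated, row-normalized kernel used to carry the diffusion."""
    n = W.shape[0]
    M = W.copy()
    np.fill_diagonal(M, -np.inf)
    order = np.argsort(-M, axis=1, kind="stable")[:, :k]
    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), k)
    S[rows, order.ravel()] = W[rows, order.ravel()]
    return row_normalize(S)


def integrate_snf(
    X1: np.ndarray,
    X2: np.ndarray,
    k: int = 20,
    mu: float = 0.5,
    n_iter: int = 20,
    K_eigs: int = 20,
    k_out: int = 10,
    seed: int = 0,
) -> IntegrationResult:
    """Similarity network fusion with a Laplacian spectral embedding.

    Modality kernels use a locally adaptive heat kernel; cross-diffusion
    updates P1 <- S1 P2 S1' (and symmetrically) exchange information for
    ``n_iter`` rounds; the fused affinity is eigendecomposed through the
    unnormalized Laplacian L_u = D - A, keeping the eigenvectors of the
    K_eigs smallest nontrivial eigenvalues as the embedding (the constant
    first eigenvector is dropped).
    """
    n = X1.shape[0]
    if K_eigs >= n:
        raise ValueError("K_eigs must be < number of cells")
    Ws = [_snf_affinity(np.asarray(X, float), k, mu) for X in (X1, X2)]
    Ps = [_snf_status(W) for W in Ws]
    Ss = [_snf_local(W, k) for W in Ws]
    eye = np.eye(X1.shape[0])
    for _ in range(n_iter):
        P0 = Ss[0] @ Ps[1] @ Ss[0].T
        P1 = Ss[1] @ Ps[0] @ Ss[1].T
        # symmetrize and re-add self-affinity: keeps the diffusion from
        # collapsing onto dominant local cliques
        Ps = [(P0 + P0.T) / 2.0 + eye, (P1 + P1.T) / 2.0 + eye]
    A = (Ps[0] + Ps[1]) / 2.0
    A = row_normalize(A)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)

    L = np.diag(A.sum(axis=1)) - A
    vals, vecs = scipy.linalg.eigh(L)
    # drop the trivial constant mode: project it out of the bottom
    # eigenspace (robust when a disconnected fused graph makes the zero
    # eigenvalue degenerate and eigh returns an arbitrary null basis)
    B = vecs[:, : K_eigs + 1]
    c = np.full(B.shape[0], 1.0 / np.sqrt(B.shape[0]))
    B = B - np.outer(c, c @ B)
    U, sv, _ = np.linalg.svd(B, full_matrices=False)
    emb = U[:, :K_eigs]
    return IntegrationResult(
        graph=knn_graph(emb, k=k_out, provenance="snf"),
        embedding=Embedding(emb, method="snf"),
        extras={"fused_affinity": A, "laplacian_eigenvalues": vals},
    )


# ---------------------------------------------------------------------------
# Grassmann joint embedding
# ---------------------------------------------------------------------------

def _normalized_laplacian(W: np.ndarray) -> np.ndarray:
    d = W.sum(axis=1)
    inv = np.zeros_like(d)
    nz = d > 0
    inv[nz] = 1.0 / np.sqrt(d[nz])
    L = -W * inv[:, None] * inv[None, :]
    np.fill_diagonal(L, np.where(nz, 1.0 + np.diag(L), 0.0))
    return (L + L.T) / 2.0


def _heat_kernel_knn(X: np.ndarray, k: int, t: Optional[float]) -> np.ndarray:
    D = pairwise_distances(X)
    if t is None:
        off = D[np.triu_indices_from(D, 1)]
        pos = off[off > 0]
        t = float(np.median(pos)) if pos.size else 1.0
    S = np.exp(-(D ** 2) / (2.0 * t * t))
    n = S.shape[0]
    M = S.copy()
    np.fill_diagonal(M, -np.inf)
    order = np.argsort(-M, axis=1, kind="stable")[:, :k]
    W = np.zeros_like(S)
    rows = np.repeat(np.arange(n), k)
    W[rows, order.ravel()] = S[rows, order.ravel()]
    W = np.maximum(W, W.T)  # symmetrize by max
    np.fill_diagonal(W, 0.0)
    return W


def integrate_grassmann(
    X1: np.ndarray,
    X2: np.ndarray,
    k: int = 20,
    t: Optional[float] = None,
    alpha: float = 0.5,
    K_eigs: int = 20,
    k_out: int = 10,
    seed: int = 0,
) -> IntegrationResult:
    """Joint subspace embedding trading modality structure vs agreement.

    Per modality, a k-NN heat-kernel graph yields a normalized Laplacian
    whose K_eigs bottom eigenvectors U^m span the modality subspace; the
    merged operator L_mod = sum_m L_n^m - alpha * sum_m U^m U^m' balances
    preserving each modality's spectral structure (first term) against
    pulling the subspaces together (second term).  Its bottom K_eigs
    eigenvectors are the shared embedding.
    """
    n = X1.shape[0]
    if K_eigs >= n:
        raise ValueError("K_eigs must be < number of cells")
    Ls, Us = [], []
    for X in (X1, X2):
        W = _heat_kernel_knn(np.asarray(X, float), k, t)
        L = _normalized_laplacian(W)
        vals, vecs = scipy.linalg.eigh(L)
        Ls.append(L)
        Us.append(vecs[:, :K_eigs])
    L_mod = Ls[0] + Ls[1] - alpha * (Us[0] @ Us[0].T + Us[1] @ Us[1].T)
    L_mod = (L_mod + L_mod.T) / 2.0
    vals, vecs = scipy.linalg.eigh(L_mod)
    emb = vecs[:, :K_eigs]
    return IntegrationResult(
        graph=knn_graph(emb, k=k_out, provenance="grassmann"),
        embedding=Embedding(emb, method="grassmann"),
        extras={"modality_laplacians": Ls, "L_mod": L_mod},
    )


# ---------------------------------------------------------------------------
# integrated diffusion
# ---------------------------------------------------------------------------

def _spectral_cluster(X: np.ndarray, n_clusters: int, k: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    W = _heat_kernel_knn(X, k, None)
    L = _normalized_laplacian(W)
    _, vecs = scipy.linalg.eigh(L)
    emb = vecs[:, :n_clusters]
    norm = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.maximum(norm, 1e-12)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(emb)


def _local_denoise(X: np.ndarray, labels: np.ndarray, var_keep: float = 0.9) -> np.ndarray:
    out = X.copy()
    for c in np.unique(labels):
        m = labels == c
        sub = X[m]
        if m.sum() < 3:
            continue
        mu = sub.mean(axis=0)
        Uc, sv, Vt = np.linalg.svd(sub - mu, full_matrices=False)
        var = sv ** 2
        if var.sum() == 0:
            continue
        r = int(np.searchsorted(np.cumsum(var) / var.sum(), var_keep) + 1)
        out[m] = mu + (Uc[:, :r] * sv[:r]) @ Vt[:r]
    return out


def _diffusion_operator(X: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic operator from a symmetric adaptive Gaussian kernel."""
    D = pairwise_distances(X)
    Dn = D.copy()
    np.fill_diagonal(Dn, np.inf)
    sigma = np.sort(Dn, axis=1)[:, k - 1]
    sigma = np.maximum(sigma, 1e-12)
    K = np.exp(-(D ** 2) / (sigma[:, None] * sigma[None, :]))
    return row_normalize(K)


def spectral_entropy(eigvals: np.ndarray, t: int) -> float:
    """Shannon entropy of the normalized |eigenvalue|^t distribution."""
    lam = np.abs(np.asarray(eigvals)).astype(float) ** t
    s = lam.sum()
    if s <= 0:
        return 0.0
    p = lam / s
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _entropy_time(eigvals: np.ndarray, t_max: int = 16, rel_drop: float = 0.05) -> int:
    """Elbow of spectral entropy: the smallest t whose entropy decrement
    falls below ``rel_drop`` of the total entropy decay up to t_max."""
    H = [spectral_entropy(eigvals, t) for t in range(1, t_max + 1)]
    total = H[0] - H[-1]
    if total <= 0:
        return 1
    for t in range(2, t_max + 1):
        if H[t - 2] - H[t - 1] < rel_drop * total:
            return t
    return t_max


def _operator_eigvals(P: np.ndarray) -> np.ndarray:
    return np.linalg.eigvals(P)


def integrate_integrated_diffusion(
    X1: np.ndarray,
    X2: np.ndarray,
    n_clusters: int = 4,
    k: int = 20,
    K_eigs: int = 20,
    t_max: int = 16,
    k_out: int = 10,
    seed: int = 0,
) -> IntegrationResult:
    """Alternating diffusion of locally denoised modality operators.

    Each modality is denoised by per-cluster truncated SVD (clusters from
    spectral clustering, components covering >= 90% variance), converted to
    a row-stochastic diffusion operator, and assigned a diffusion time by
    the spectral-entropy elbow.  The times are reduced by their ratio and
    the joint operator P_j = P_1^{t_1} P_2^{t_2} is built, then itself
    powered by the same entropy rule; the top-K_eigs eigenvectors of the
    final operator are the embedding.
    """
    n = X1.shape[0]
    if K_eigs >= n:
        raise ValueError("K_eigs must be < number of cells")
    ops, times = [], []
    for i, X in enumerate((X1, X2)):
        X = np.asarray(X, float)
        labels = _spectral_cluster(X, min(n_clusters, n - 1), k, seed + i)
        Xd = _local_denoise(X, labels)
        P = _diffusion_operator(Xd, min(k, n - 1))
        ops.append(P)
        times.append(_entropy_time(_operator_eigvals(P), t_max))
    t1, t2 = times
    base = min(t1, t2)
    t1, t2 = max(1, round(t1 / base)), max(1, round(t2 / base))
    P_j = matrix_power(ops[0], t1) @ matrix_power(ops[1], t2)
    t_j = _entropy_time(_operator_eigvals(P_j), t_max)
    P_j = matrix_power(P_j, t_j)

    vals, vecs = np.linalg.eig(P_j)
    order = np.argsort(-np.abs(vals), kind="stable")[:K_eigs]
    emb = np.real(vecs[:, order])
    return IntegrationResult(
        graph=knn_graph(emb, k=k_out, provenance="intdiff"),
        embedding=Embedding(emb, method="intdiff"),
        transition=TransitionMatrix(np.real(P_j) / np.real(P_j).sum(axis=1, keepdims=True), kind="joint-diffusion"),
        extras={"t1": t1, "t2": t2, "t_joint": t_j},
    )


# ---------------------------------------------------------------------------
# PRECISE principal vectors
# ---------------------------------------------------------------------------

def integrate_precise(
    X1: np.ndarray,
    X2: np.ndarray,
    n_pv: int = 30,
    mode: str = "principal_vectors",
    k_out: int = 10,
    seed: int = 0,
) -> IntegrationResult:
    """Align the modalities' principal subspaces into principal vectors.

    The SVD of the cross-product of the two PCA loading matrices pairs up
    directions (principal vectors) ordered by the cosine of their principal
    angles.  ``principal_vectors`` projects the first modality onto its own
    side of each pair; ``consensus`` projects onto the geodesic midpoint of
    each pair.
    """
    if mode not in ("principal_vectors", "consensus"):
        raise ValueError(f"unknown mode {mode!r}")
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    n, d = X1.shape
    n_pv = int(min(n_pv, d, n - 1))
    from sklearn.decomposition import PCA

    V1 = PCA(n_components=n_pv, svd_solver="full", random_state=seed).fit(X1).components_.T
    V2 = PCA(n_components=n_pv, svd_solver="full", random_state=seed).fit(X2).components_.T
    A, sig, Bt = np.linalg.svd(V1.T @ V2)
    Q1 = V1 @ A
    Q2 = V2 @ Bt.T
    cosines = np.clip(sig, 0.0, 1.0)

    if mode == "principal_vectors":
        basis = Q1
    else:
        mid = Q1 + Q2
        norms = np.linalg.norm(mid, axis=0)
        # antipodal pairs (cosine ~ -1) have no midpoint; keep the X1 side
        basis = np.where(norms > 1e-8, mid / np.maximum(norms, 1e-8), Q1)
    proj = (X1 - X1.mean(axis=0)) @ basis
    return IntegrationResult(
        graph=knn_graph(proj, k=k_out, provenance=f"precise:{mode}"),
        embedding=Embedding(proj, method=f"precise:{mode}"),
        extras={"cosines": cosines, "pv_1": Q1, "pv_2": Q2},
    )


# ---------------------------------------------------------------------------
# weighted nearest neighbors
# ---------------------------------------------------------------------------

def integrate_wnn(
    X1: np.ndarray,
    X2: np.ndarray,
    k: int = 10,
    n_pcs: int = 50,
    k_out: int = 10,
    seed: int = 0,
) -> IntegrationResult:
    """Per-cell weighted combination of modality affinities.

    Within- and cross-modality neighbor predictions of each cell's PCA
    profile measure how informative each modality is locally; an
    exponential kernel of the prediction errors (bandwidth: distance to the
    nearest neighbor) gives per-cell modality affinities, softmaxed into
    weights summing to 1.  The joint similarity is the weight-blended pair
    of modality kernels, and the output graph keeps its top-k entries.
    """
    embs = [pca_embed(np.asarray(X, float), n_comps=n_pcs, seed=seed) for X in (X1, X2)]
    n = embs[0].shape[0]
    kk = min(k, n - 1)
    nbrs = []
    sigmas = []
    for Z in embs:
        idx, dist = knn_indices(Z, kk)
        nbrs.append(idx)
        sigmas.append(np.maximum(dist[:, 0], 1e-12))

    ratios = np.zeros((n, 2))
    for m, Z in enumerate(embs):
        within = Z[nbrs[m]].mean(axis=1)
        cross = Z[nbrs[1 - m]].mean(axis=1)
        err_w = np.linalg.norm(Z - within, axis=1)
        err_c = np.linalg.norm(Z - cross, axis=1)
        ratios[:, m] = (err_c - err_w) / sigmas[m]
    e = np.exp(ratios - ratios.max(axis=1, keepdims=True))
    weights = e / e.sum(axis=1, keepdims=True)

    S = np.zeros((n, n))
    for m, Z in enumerate(embs):
        D = pairwise_distances(Z)
        K = np.exp(-D / sigmas[m][:, None])
        S += weights[:, m][:, None] * K
    graph = knn_graph_from_similarity(S, k=k_out, provenance="wnn")
    return IntegrationResult(graph=graph, extras={"modality_weights": weights, "joint_similarity": S})


# ---------------------------------------------------------------------------
# shared factor model
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    Z: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    objective: np.ndarray
    converged: bool

    @property
    def K(self) -> int:
        return self.Z.shape[1]


def integrate_factor_model(
    X1: np.ndarray,
    X2: np.ndarray,
    K: int = 50,
    max_iter: int = 500,
    tol: float = 1e-9,
    ridge: float = 1e-8,
    k_out: int = 10,
    seed: int = 0,
) -> IntegrationResult:
    """Shared-factor decomposition X^m = Z W^m' + eps^m by alternating
    least squares with a small ridge; the shared factors Z are the joint
    embedding.  The (penalized) objective is non-increasing by construction
    and iteration stops when its relative change drops below ``tol``."""
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    n = X1.shape[0]
    if K > min(n, X1.shape[1], X2.shape[1]):
        raise ValueError(f"K={K} exceeds the smallest data dimension")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, K)) * 0.01
    eye = np.eye(K)

    def solve_w(X, Z):
        return np.linalg.solve(Z.T @ Z + ridge * eye, Z.T @ X).T

    obj = []
    converged = False
    for _ in range(max_iter):
        W1 = solve_w(X1, Z)
        W2 = solve_w(X2, Z)
        G = W1.T @ W1 + W2.T @ W2 + ridge * eye
        Z = np.linalg.solve(G, (X1 @ W1 + X2 @ W2).T).T
        val = (
            np.sum((X1 - Z @ W1.T) ** 2)
            + np.sum((X2 - Z @ W2.T) ** 2)
            + ridge * (np.sum(Z ** 2) + np.sum(W1 ** 2) + np.sum(W2 ** 2))
        )
        obj.append(val)
        if len(obj) > 1 and abs(obj[-2] - obj[-1]) <= tol * max(obj[-2], 1e-300):
            converged = True
            break
    model = FactorModel(Z=Z, W1=W1, W2=W2, objective=np.asarray(obj), converged=converged)
    return IntegrationResult(
        graph=knn_graph(Z, k=k_out, provenance="factor"),
        embedding=Embedding(Z, method="factor"),
        extras={"model": model},
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

METHODS: Dict[str, Callable] = {
    "unintegrated": integrate_unintegrated,
    "concat": integrate_concat,
    "sum": integrate_sum,
    "cellrank": integrate_cellrank,
    "snf": integrate_snf,
    "grassmann": integrate_grassmann,
    "intdiff": integrate_integrated_diffusion,
    "precise": integrate_precise,
    "precise_consensus": lambda X1, X2, **kw: integrate_precise(X1, X2, mode="consensus", **kw),
    "wnn": integrate_wnn,
    "factor": integrate_factor_model,
}


def run_method(name: str, X1: np.ndarray, X2: Optional[np.ndarray] = None, **params) -> IntegrationResult:
    """Dispatch an integration strategy by registry name.

    ``cellrank`` is special-cased: it expects ``X1 = Ms`` (spliced moments)
    and ``X2 = V`` (velocity) and builds its two Markov operators from the
    unintegrated expression graph.
    """
    if name not in METHODS:
        raise KeyError(f"unknown method {name!r}; registered: {sorted(METHODS)}")
    if name == "unintegrated":
        return integrate_unintegrated(X1, **params)
    if name == "cellrank":
        lam = params.pop("lam")
        scheme = params.pop("scheme", "cosine")
        k = params.pop("k", 10)
        base = integrate_unintegrated(X1, k=k, **params)
        P_s = expression_transition(base.graph)
        P_v = velocity_transition(base.graph, X1, X2, scheme=scheme)
        return integrate_cellrank(P_s, P_v, lam=lam, k=k)
    return METHODS[name](X1, X2, **params)
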