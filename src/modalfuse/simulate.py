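"""Synthetic paired unspliced/spliced data with known kinetics.

Cells are placed along a milestone trajectory (chain, bifurcation, or
cycle).  Each gene follows the two-stage splicing ODE

    du/dt = alpha(t) - beta * u
    ds/dt = beta * u - gamma * s

with transcription alpha switched on only while the cell's path traverses
the gene's active edges (constitutive genes are always on).  The latent
(u, s) trajectories are propagated analytically, segment by segment, so the
stored ground truth solves the ODE exactly; the true velocity
v = beta*u - gamma*s is stored alongside.  Observed counts are sampled from
the latent abundances under a capture model, with unspliced capture
efficiency below spliced, reproducing the higher sparsity of pre-mRNA
measurements.

Batch effects and condition (perturbation) labels are layered on top so
every downstream stage -- correction, velocity, integration, trajectory and
classification scoring -- can be exercised against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .bundle import ModalityBundle, make_bundle

NOISE_MODELS = ("poisson", "binomial_capture")


@dataclass
class TrajectoryTopology:
    """Milestone network with a root and per-edge lengths (time units)."""

    milestones: List[str]
    edges: List[Tuple[str, str]]
    root: str
    edge_lengths: Optional[List[float]] = None

    def __post_init__(self) -> None:
        if self.edge_lengths is None:
            self.edge_lengths = [4.0] * len(self.edges)
        if len(self.edge_lengths) != len(self.edges):
            raise ValueError("edge_lengths must match edges")
        if self.root not in self.milestones:
            raise ValueError(f"root {self.root!r} not among milestones")
        g = self.graph()
        if len(self.milestones) > 1 and not nx.is_weakly_connected(g):
            raise ValueError("topology is disconnected")
        if nx.is_directed_acyclic_graph(g) and g.in_degree(self.root) != 0:
            raise ValueError("root of a tree topology must have no incoming edge")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.milestones)
        for (a, b), ln in zip(self.edges, self.edge_lengths):
            g.add_edge(a, b, length=ln)
        return g

    def path_to_edge(self, edge_idx: int) -> List[int]:
        """Edge indices of the shortest directed path root -> source of edge."""
        src = self.edges[edge_idx][0]
        g = self.graph()
        nodes = nx.shortest_path(g, self.root, src, weight="length")
        idx = {e: i for i, e in enumerate(self.edges)}
        return [idx[(a, b)] for a, b in zip(nodes[:-1], nodes[1:])]


def linear_topology(n_milestones: int = 3, edge_length: float = 4.0) -> TrajectoryTopology:
    names = [f"M{i}" for i in range(n_milestones)]
    edges = list(zip(names[:-1], names[1:]))
    return TrajectoryTopology(names, edges, root=names[0], edge_lengths=[edge_length] * len(edges))


def bifurcation_topology(edge_length: float = 4.0) -> TrajectoryTopology:
    names = ["root", "early", "branch_a", "branch_b"]
    edges = [("root", "early"), ("early", "branch_a"), ("early", "branch_b")]
    return TrajectoryTopology(names, edges, root="root", edge_lengths=[edge_length] * 3)


def cycle_topology(edge_length: float = 4.0) -> TrajectoryTopology:
    """Three-phase cell-cycle loop G1 -> S -> G2M -> G1."""
    names = ["G1", "S", "G2M"]
    edges = [("G1", "S"), ("S", "G2M"), ("G2M", "G1")]
    return TrajectoryTopology(names, edges, root="G1", edge_lengths=[edge_length] * 3)


@dataclass
class KineticParams:
    """Per-gene splicing kinetics and capture efficiencies.

    ``active_edges[g]`` is the set of topology edge indices on which gene g
    transcribes (None = constitutive); transcription switches on/off at the
    times the cell's path enters/leaves those edges.  Capture efficiencies
    satisfy ``p_u <= p_s`` so the unspliced layer is the sparser one.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    active_edges: List[Optional[frozenset]] = field(default_factory=list)
    p_s: float = 0.3
    p_u: float = 0.1

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.alpha < 0) or np.any(self.beta <= 0) or np.any(self.gamma <= 0):
            raise ValueError("rates must be positive (alpha may be zero)")
        if not (0 < self.p_u <= self.p_s <= 1):
            raise ValueError("need 0 < p_u <= p_s <= 1")
        if not self.active_edges:
            self.active_edges = [None] * len(self.alpha)
        # closed forms below assume beta != gamma per gene
        clash = np.isclose(self.beta, self.gamma)
        self.beta = np.where(clash, self.beta * 1.001, self.beta)

    @property
    def n_genes(self) -> int:
        return len(self.alpha)


def default_kinetics(
    n_genes: int,
    topology: TrajectoryTopology,
    seed: int = 0,
    frac_constitutive: float = 0.4,
    p_s: float = 0.3,
    p_u: float = 0.1,
) -> KineticParams:
    """Draw kinetics typical of moderately expressed genes.

    Steady-state spliced abundance alpha/gamma is on the order of 10-40
    molecules, which after capture yields the few-count sparsity of plate-
    and droplet-based assays.
    """
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(3.0, 9.0, n_genes)
    beta = rng.uniform(0.4, 0.7, n_genes)
    gamma = rng.uniform(0.2, 0.35, n_genes)
    n_edges = len(topology.edges)
    active: List[Optional[frozenset]] = []
    for g in range(n_genes):
        if rng.random() < frac_constitutive:
            active.append(None)
        else:
            k = rng.integers(1, max(2, n_edges))
            active.append(frozenset(rng.choice(n_edges, size=min(k, n_edges), replace=False).tolist()))
    return KineticParams(alpha, beta, gamma, active, p_s=p_s, p_u=p_u)


# ---------------------------------------------------------------------------
# ODE propagation
# ---------------------------------------------------------------------------

def _step(u0, s0, alpha, beta, gamma, tau):
    """Advance (u, s) by time tau under constant alpha; exact closed form."""
    tau = np.asarray(tau, dtype=float)
    if tau.ndim == 1:
        tau = tau[:, None]
    eb = np.exp(-beta * tau)
    eg = np.exp(-gamma * tau)
    c = u0 - alpha / beta
    u = alpha / beta + c * eb
    coef = beta * c / (gamma - beta)
    s = alpha / gamma + (s0 - alpha / gamma - coef) * eg + coef * eb
    return u, s


def _segment_alpha(params: KineticParams, edge_idx: int) -> np.ndarray:
    mask = np.array(
        [ae is None or edge_idx in ae for ae in params.active_edges], dtype=float
    )
    return params.alpha * mask


def _counts_rng(seed: int) -> np.random.Generator:
    # dedicated child stream so resampling after expected-count edits is
    # bit-reproducible across simulate_kinetics / add_batch_effects
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))


def _sample_counts(u_latent, s_latent, noise_model, p_u, p_s, rng):
    if noise_model == "poisson":
        U = rng.poisson(p_u * u_latent).astype(float)
        S = rng.poisson(p_s * s_latent).astype(float)
    elif noise_model == "binomial_capture":
        U = rng.binomial(rng.poisson(u_latent), p_u).astype(float)
        S = rng.binomial(rng.poisson(s_latent), p_s).astype(float)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}; choose from {NOISE_MODELS}")
    return U, S


def alpha_profile(params: KineticParams, topology: TrajectoryTopology, edge_idx: int):
    """Piecewise-constant transcription rate along the path to ``edge_idx``.

    Returns ``(breaks, alphas)``: segment end times (cumulative) and the
    (n_segments, n_genes) rate matrix -- the per-gene switch times are the
    breakpoints at which a gene's column changes.
    """
    path = topology.path_to_edge(edge_idx) + [edge_idx]
    breaks = np.cumsum([topology.edge_lengths[e] for e in path])
    alphas = np.stack([_segment_alpha(params, e) for e in path])
    return breaks, alphas


def simulate_kinetics(
    topology: TrajectoryTopology,
    params: KineticParams,
    n_cells: int,
    n_genes: Optional[int] = None,
    noise_model: str = "binomial_capture",
    seed: int = 0,
) -> ModalityBundle:
    """Simulate a paired unspliced/spliced bundle along a trajectory.

    Cells are distributed over edges proportionally to edge length and
    uniformly within an edge.  The returned bundle stores the exact latent
    ``u``, ``s`` and velocity ``v = beta*u - gamma*s`` matrices under
    ``uns['latent_u'|'latent_s'|'latent_v']`` together with the topology and
    parameters, and annotates per-cell milestone edge, fraction, cluster
    label and latent time in ``cell_meta``.
    """
    if n_genes is not None and n_genes != params.n_genes:
        raise ValueError("n_genes disagrees with params")
    d = params.n_genes
    n_edges = len(topology.edges)
    if n_cells < len(topology.milestones):
        raise ValueError("need at least one cell per milestone")
    if noise_model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {noise_model!r}; choose from {NOISE_MODELS}")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    lengths = np.asarray(topology.edge_lengths, dtype=float)
    edge_of_cell = rng.choice(n_edges, size=n_cells, p=lengths / lengths.sum())
    frac = rng.uniform(0.0, 1.0, n_cells)

    # state at the entry of each edge: propagate along the root path once
    entry_u = np.zeros((n_edges, d))
    entry_s = np.zeros((n_edges, d))
    entry_t = np.zeros(n_edges)
    alpha0 = np.array(
        [params.alpha[g] if params.active_edges[g] is None else 0.0 for g in range(d)]
    )
    u_root = alpha0 / params.beta
    s_root = alpha0 / params.gamma
    for e in range(n_edges):
        path = topology.path_to_edge(e)
        u, s, t = u_root.copy(), s_root.copy(), 0.0
        for pe in path:
            a = _segment_alpha(params, pe)
            u, s = _step(u, s, a, params.beta, params.gamma, np.array([lengths[pe]]))
            u, s = u[0], s[0]
            t += lengths[pe]
        entry_u[e], entry_s[e], entry_t[e] = u, s, t

    latent_u = np.zeros((n_cells, d))
    latent_s = np.zeros((n_cells, d))
    latent_t = np.zeros(n_cells)
    for e in range(n_edges):
        cells = np.where(edge_of_cell == e)[0]
        if cells.size == 0:
            continue
        tau = frac[cells] * lengths[e]
        a = _segment_alpha(params, e)
        u, s = _step(entry_u[e], entry_s[e], a, params.beta, params.gamma, tau)
        latent_u[cells] = u
        latent_s[cells] = s
        latent_t[cells] = entry_t[e] + tau
    latent_v = params.beta * latent_u - params.gamma * latent_s

    U, S = _sample_counts(
        latent_u, latent_s, noise_model, params.p_u, params.p_s, _counts_rng(seed)
    )

    src = [topology.edges[e][0] for e in edge_of_cell]
    tgt = [topology.edges[e][1] for e in edge_of_cell]
    cluster = [s if f < 0.5 else t for s, t, f in zip(src, tgt, frac)]
    cell_meta = pd.DataFrame(
        {
            "cluster_label": cluster,
            "is_root_cluster": [c == topology.root for c in cluster],
            "edge_source": src,
            "edge_target": tgt,
            "edge_fraction": frac,
            "latent_time": latent_t,
        }
    )
    bundle = make_bundle(
        S,
        U,
        cell_meta=cell_meta,
        uns={
            "latent_u": latent_u,
            "latent_s": latent_s,
            "latent_v": latent_v,
            "topology": topology,
            "kinetics": params,
            "noise_model": noise_model,
            "seed": seed,
        },
    )
    return bundle


def add_batch_effects(
    bundle: ModalityBundle,
    batch_assignment: Sequence,
    log_fold_shift: Optional[Mapping[str, np.ndarray]] = None,
    depth_factor: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> ModalityBundle:
    """Apply multiplicative batch shifts to the expected counts and resample.

    The same per-gene factor ``exp(shift) * depth`` multiplies the latent
    unspliced and spliced abundances of a cell, so the within-batch u/s
    phase-space relationship is preserved; counts are then redrawn under the
    bundle's original noise model.  With zero shift and unit depth, passing
    the seed used for ``simulate_kinetics`` reproduces the counts exactly.
    """
    batch = np.asarray(batch_assignment)
    if batch.shape[0] != bundle.n_cells:
        raise ValueError("batch_assignment must cover all cells")
    for key in ("latent_u", "latent_s", "kinetics"):
        if key not in bundle.uns:
            raise ValueError("bundle lacks simulation ground truth; cannot resample")
    params: KineticParams = bundle.uns["kinetics"]
    d = bundle.n_genes
    factor = np.ones((bundle.n_cells, d))
    for b in np.unique(batch):
        mask = batch == b
        f = np.ones(d)
        if log_fold_shift and b in log_fold_shift:
            f = f * np.exp(np.asarray(log_fold_shift[b], dtype=float))
        if depth_factor and b in depth_factor:
            f = f * float(depth_factor[b])
        factor[mask] = f
    latent_u = bundle.uns["latent_u"] * factor
    latent_s = bundle.uns["latent_s"] * factor
    U, S = _sample_counts(
        latent_u,
        latent_s,
        bundle.uns.get("noise_model", "binomial_capture"),
        params.p_u,
        params.p_s,
        _counts_rng(seed),
    )
    out = bundle.copy()
    out.layers["spliced"] = S
    out.layers["unspliced"] = U
    out.cell_meta = out.cell_meta.assign(batch=batch)
    out.uns["latent_u"] = latent_u
    out.uns["latent_s"] = latent_s
    out.uns["latent_v"] = params.beta * latent_u - params.gamma * latent_s
    return out


def assign_condition_labels(
    bundle: ModalityBundle,
    signal_genes: Sequence,
    effect_size: float,
    balance: float = 0.5,
    layers: Sequence[str] = ("spliced", "unspliced"),
    seed: int = 0,
) -> ModalityBundle:
    """Label a fraction of cells as perturbed and shift their signal genes.

    ``effect_size`` is a natural-log fold change applied multiplicatively to
    the counts of ``signal_genes`` in the stated layers of labeled cells;
    restricting ``layers`` to a single modality builds "complementary
    signal" fixtures where only one layer carries the class information.
    ``effect_size == 0`` leaves the data untouched, so labels are
    independent of expression.
    """
    if not 0 < balance < 1:
        raise ValueError("balance must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    n = bundle.n_cells
    n_lab = int(round(balance * n))
    labeled = np.zeros(n, dtype=bool)
    labeled[rng.choice(n, size=n_lab, replace=False)] = True

    gene_index = pd.Index(bundle.gene_ids)
    sig = np.asarray(signal_genes)
    if sig.dtype.kind in ("U", "S", "O"):
        cols = gene_index.get_indexer(sig)
        if (cols < 0).any():
            raise KeyError(f"unknown signal genes: {sig[cols < 0]}")
    else:
        cols = sig.astype(int)

    out = bundle.copy()
    fc = float(np.exp(effect_size))
    if effect_size != 0:
        for layer in layers:
            mat = out.layers[layer]
            mat[np.ix_(labeled, cols)] *= fc
    out.cell_meta = out.cell_meta.assign(
        condition_label=np.where(labeled, "perturbed", "control")
    )
    out.uns["signal_genes"] = list(map(str, gene_index[cols]))
    out.uns["signal_layers"] = tuple(layers)
    return out


# ---------------------------------------------------------------------------
# study-condition fixtures
# ---------------------------------------------------------------------------

def complementary_bifurcation_bundle(
    seed: int = 0,
    n_cells: int = 300,
    n_genes: int = 80,
    branch_length: float = 1.0,
    backbone_length: float = 4.0,
    p_s: float = 0.3,
    p_u: float = 0.25,
) -> ModalityBundle:
    """Bifurcation whose branch identity is visible mainly in unspliced.

    Branch-specific genes are modeled as strongly induced immediate-early
    programs with slow splicing: nascent (unspliced) transcripts rise
    linearly right after branch entry while mature (spliced) ones
    accumulate only quadratically, so over a short branch the spliced
    layer barely separates the two fates while the unspliced layer does.
    Backbone and constitutive genes have ordinary kinetics and are well
    captured by the spliced layer -- the two modalities carry
    complementary parts of the trajectory.
    """
    topo = TrajectoryTopology(
        ["root", "early", "branch_a", "branch_b"],
        [("root", "early"), ("early", "branch_a"), ("early", "branch_b")],
        root="root",
        edge_lengths=[backbone_length, branch_length, branch_length],
    )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
    n_const = int(0.3 * n_genes)
    n_backbone = int(0.2 * n_genes)
    n_branch = (n_genes - n_const - n_backbone) // 2
    groups = (
        ["const"] * n_const
        + ["backbone"] * n_backbone
        + ["a"] * n_branch
        + ["b"] * (n_genes - n_const - n_backbone - n_branch)
    )
    rng.shuffle(groups)
    alpha = np.empty(n_genes)
    beta = np.empty(n_genes)
    gamma = np.empty(n_genes)
    for g, grp in enumerate(groups):
        if grp in ("a", "b"):  # immediate-early: strong, slowly spliced
            alpha[g] = rng.uniform(20, 35)
            beta[g] = rng.uniform(0.25, 0.35)
            gamma[g] = rng.uniform(0.25, 0.35)
        else:
            alpha[g] = rng.uniform(3, 9)
            beta[g] = rng.uniform(0.4, 0.7)
            gamma[g] = rng.uniform(0.2, 0.35)
    amap = {"const": None, "backbone": frozenset({0}), "a": frozenset({1}), "b": frozenset({2})}
    params = KineticParams(alpha, beta, gamma, [amap[g] for g in groups], p_s=p_s, p_u=p_u)
    return simulate_kinetics(topo, params, n_cells=n_cells, seed=seed)


def complementary_signal_bundle(
    seed: int = 0,
    n_cells: int = 400,
    n_genes: int = 80,
    n_signal: int = 12,
    effect_unspliced: float = 1.5,
    effect_spliced: float = 0.4,
    balance: float = 0.5,
) -> ModalityBundle:
    """Bifurcation dataset with an early transcriptional response.

    Emulates a stimulation experiment sampled shortly after perturbation:
    the induced genes are strongly shifted in the unspliced (nascent)
    layer but only weakly in the spliced layer, where mature transcripts
    have not yet accumulated.  The class signal is therefore split across
    layers -- a spliced-only analysis sees a faint echo of it, while
    strategies that integrate both layers see the full response.
    """
    topo = bifurcation_topology()
    params = default_kinetics(n_genes, topo, seed=seed)
    bundle = simulate_kinetics(topo, params, n_cells=n_cells, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    genes = rng.choice(n_genes, size=n_signal, replace=False)
    bundle = assign_condition_labels(
        bundle, genes, effect_unspliced, balance, layers=("unspliced",), seed=seed
    )
    labels = bundle.cell_meta["condition_label"].copy()
    bundle = assign_condition_labels(
        bundle, genes, effect_spliced, balance, layers=("spliced",), seed=seed
    )
    assert (bundle.cell_meta["condition_label"] == labels).all()
    return bundle
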