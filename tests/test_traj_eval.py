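import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from modalfuse.bundle import NeighborGraph
from modalfuse.simulate import (
    bifurcation_topology,
    cycle_topology,
    default_kinetics,
    linear_topology,
    simulate_kinetics,
)
from modalfuse.traj_eval import (
    TrajectoryGraph,
    cell_distance_correlation,
    cluster_connectivity,
    diffusion_pseudotime,
    feature_importance_correlation,
    predict_trajectory,
    reference_from_bundle,
    score_trajectory,
    ti_score,
)


def _path_graph(n):
    A = sp.lil_matrix((n, n))
    for i in range(n - 1):
        A[i, i + 1] = 1.0
        A[i + 1, i] = 1.0
    return NeighborGraph(sp.csr_matrix(A), k=2)


def _linear_traj(fracs, milestones=("A", "B")):
    n = len(fracs)
    pos = pd.DataFrame({"source": [milestones[0]] * n, "target": [milestones[1]] * n, "fraction": fracs})
    return TrajectoryGraph(
        milestones=list(milestones),
        edges=[(milestones[0], milestones[1])],
        connectivity=[1.0],
        root=milestones[0],
        cell_positions=pos,
    )


class TestClusterConnectivity:
    def test_disconnected_blobs_zero_connectivity(self):
        A = sp.block_diag([np.ones((5, 5)) - np.eye(5)] * 2).tocsr()
        g = NeighborGraph(A, k=4)
        conn = cluster_connectivity(g, ["a"] * 5 + ["b"] * 5)
        assert conn[("a", "b")] == 0.0

    def test_complete_bipartite_capped_at_one(self):
        n_a, n_b = 5, 5
        A = np.zeros((10, 10))
        A[:n_a, n_a:] = 1.0
        A[n_a:, :n_a] = 1.0
        g = NeighborGraph(sp.csr_matrix(A), k=5)
        conn = cluster_connectivity(g, ["a"] * n_a + ["b"] * n_b)
        assert conn[("a", "b")] == 1.0

    def test_symmetric_in_cluster_order(self, rng):
        X = rng.normal(size=(30, 4))
        from modalfuse.integrate import integrate_unintegrated

        g = integrate_unintegrated(X, k=5, n_pcs=4).graph
        labels = rng.choice(["a", "b", "c"], 30)
        conn = cluster_connectivity(g, labels)
        conn_swap = cluster_connectivity(g, labels)
        for (a, b), v in conn.items():
            assert conn_swap[(a, b)] == v


class TestDiffusionPseudotime:
    def test_root_has_zero_pseudotime(self):
        g = _path_graph(10)
        pt = diffusion_pseudotime(g, 0, n_dcs=5)
        assert pt[0] == 0.0

    def test_strictly_increasing_along_path(self):
        g = _path_graph(10)
        pt = diffusion_pseudotime(g, 0, n_dcs=9)
        assert (np.diff(pt) > 0).all()

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(40, 6))
        from modalfuse.integrate import integrate_unintegrated

        g = integrate_unintegrated(X, k=6, n_pcs=6).graph
        pt = diffusion_pseudotime(g, 5)
        perm = rng.permutation(40)
        A_p = g.adjacency[perm][:, perm]
        g_p = NeighborGraph(A_p, k=6)
        pt_p = diffusion_pseudotime(g_p, int(np.where(perm == 5)[0][0]))
        np.testing.assert_allclose(pt_p, pt[perm], atol=1e-9)


@pytest.fixture(scope="module")
def chain():
    topo = linear_topology(3, edge_length=3.0)
    params = default_kinetics(40, topo, seed=21, frac_constitutive=0.3)
    b = simulate_kinetics(topo, params, n_cells=200, seed=21)
    from modalfuse.benchmark import prepare_inputs
    from modalfuse.integrate import integrate_unintegrated

    inputs = prepare_inputs(b)
    graph = integrate_unintegrated(inputs["log_spliced"]).graph
    return b, graph


class TestPredictTrajectory:

    def test_chain_topology_recovered_for_every_root(self, chain):
        b, graph = chain
        labels = b.cell_meta["cluster_label"].to_numpy()
        preds = predict_trajectory(graph, labels, "M0", n_roots=10, seed=0)
        assert len(preds) == 10
        for p in preds:
            assert set(p.edges) == {("M0", "M1"), ("M1", "M2")}

    def test_roots_drawn_from_root_cluster(self, chain):
        b, graph = chain
        labels = b.cell_meta["cluster_label"].to_numpy()
        preds = predict_trajectory(graph, labels, "M0", n_roots=10, seed=3)
        for p in preds:
            assert labels[p.flags["root_cell"]] == "M0"

    def test_same_seed_same_roots(self, chain):
        b, graph = chain
        labels = b.cell_meta["cluster_label"].to_numpy()
        a = predict_trajectory(graph, labels, "M0", n_roots=5, seed=9)
        c = predict_trajectory(graph, labels, "M0", n_roots=5, seed=9)
        assert [p.flags["root_cell"] for p in a] == [p.flags["root_cell"] for p in c]

    def test_impossible_threshold_flags_isolated_milestones(self, chain):
        b, graph = chain
        labels = b.cell_meta["cluster_label"].to_numpy()
        with pytest.warns(UserWarning, match="isolated"):
            preds = predict_trajectory(
                graph, labels, "M0", n_roots=1, connectivity_threshold=1.01, seed=0
            )
        ref = reference_from_bundle(b)
        score = cell_distance_correlation(ref, preds[0])
        assert np.isfinite(score)

    def test_missing_root_cluster_rejected(self, chain):
        b, graph = chain
        labels = b.cell_meta["cluster_label"].to_numpy()
        with pytest.raises(ValueError, match="absent"):
            predict_trajectory(graph, labels, "nope", seed=0)


class TestCellDistanceCorrelation:
    def test_identity_scores_one(self, rng):
        traj = _linear_traj(rng.uniform(0, 1, 30))
        assert cell_distance_correlation(traj, traj) == 1.0

    def test_reversed_linear_topology_still_one(self):
        """Distances on a line are invariant to orientation."""
        fr = np.array([0.1, 0.4, 0.6, 0.9])
        a = _linear_traj(fr)
        b = _linear_traj(1.0 - fr, milestones=("B", "A"))
        assert abs(cell_distance_correlation(a, b) - 1.0) < 1e-12

    def test_shuffled_positions_near_zero(self):
        rng = np.random.default_rng(4)
        fr = rng.uniform(0, 1, 200)
        a = _linear_traj(fr)
        b = _linear_traj(rng.permutation(fr))
        assert abs(cell_distance_correlation(a, b)) < 0.1

    def test_pair_sampling_close_to_exhaustive(self, rng):
        fr = rng.uniform(0, 1, 100)
        fr2 = np.clip(fr + rng.normal(0, 0.1, 100), 0, 1)
        a, b = _linear_traj(fr), _linear_traj(fr2)
        full = cell_distance_correlation(a, b)
        sampled = cell_distance_correlation(a, b, n_pairs_sample=2000, seed=0)
        assert abs(full - sampled) < 0.05


class TestFeatureImportanceCorrelation:
    def test_identity_scores_one(self, rng):
        fr = rng.uniform(0, 1, 80)
        traj = _linear_traj(fr)
        expr = np.column_stack([fr + rng.normal(0, 0.1, 80) for _ in range(5)])
        assert abs(feature_importance_correlation(traj, traj, expr, n_trees=50, seed=0) - 1.0) < 1e-12

    def test_noise_expression_low_correlation(self):
        vals = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            fr = rng.uniform(0, 1, 100)
            a = _linear_traj(fr)
            b = _linear_traj(rng.permutation(fr))
            expr = rng.normal(size=(100, 15))
            vals.append(feature_importance_correlation(a, b, expr, n_trees=50, seed=seed))
        assert abs(np.median(vals)) < 0.3

    def test_planted_trajectory_gene_top_scored(self, rng):
        from modalfuse.traj_eval import reference_feature_scores

        fr = rng.uniform(0, 1, 100)
        traj = _linear_traj(fr)
        expr = rng.normal(0, 1, (100, 10))
        expr[:, 3] = 5 * fr + rng.normal(0, 0.1, 100)
        scores = reference_feature_scores(traj, expr, n_trees=50, seed=0)
        assert scores.argmax() == 3

    def test_constant_scores_flagged_as_zero(self, rng):
        fr = rng.uniform(0, 1, 50)
        traj = _linear_traj(fr)
        expr = np.ones((50, 4))  # constant genes -> all scores 0
        assert feature_importance_correlation(traj, traj, expr, n_trees=20, seed=0) == 0.0


class TestTIScore:
    @pytest.mark.parametrize(
        "c,f,expected",
        [(1.0, 1.0, 1.0), (0.5, 0.5, 0.5), (0.8, 0.4, 2 * 0.8 * 0.4 / 1.2)],
    )
    def test_harmonic_mean_values(self, c, f, expected):
        assert abs(ti_score(c, f) - expected) < 1e-12

    def test_idempotent_on_diagonal(self):
        for x in np.linspace(0.05, 1.0, 12):
            assert abs(ti_score(x, x) - x) < 1e-12

    def test_negatives_clipped_to_zero(self):
        assert ti_score(-0.5, 0.8) == 0.0
        assert ti_score(0.0, 0.0) == 0.0

    def test_harmonic_below_geometric_below_arithmetic(self):
        grid = np.linspace(0.05, 1.0, 8)
        for c in grid:
            for f in grid:
                h = ti_score(c, f)
                g = np.sqrt(c * f)
                assert h <= g + 1e-12 <= (c + f) / 2 + 1e-12


class TestSelfConsistency:
    @pytest.mark.parametrize(
        "topo_fn", [lambda: linear_topology(3), bifurcation_topology, cycle_topology]
    )
    def test_reference_scores_itself_perfectly(self, topo_fn):
        topo = topo_fn()
        params = default_kinetics(30, topo, seed=13)
        b = simulate_kinetics(topo, params, n_cells=120, seed=13)
        ref = reference_from_bundle(b)
        expr = np.log1p(b.layers["spliced"][:, :10])
        score = score_trajectory(ref, ref, expr, n_trees=30, seed=0)
        assert score.C_corr == 1.0
        assert abs(score.TI_corr - 1.0) < 1e-9
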