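import numpy as np
import pytest
import scipy.linalg

from modalfuse.graphs import DegenerateInputError, pca_embed
from modalfuse.integrate import (
    METHODS,
    expression_transition,
    integrate_cellrank,
    integrate_concat,
    integrate_factor_model,
    integrate_grassmann,
    integrate_integrated_diffusion,
    integrate_precise,
    integrate_snf,
    integrate_sum,
    integrate_unintegrated,
    integrate_wnn,
    run_method,
    spectral_entropy,
    velocity_transition,
)
from modalfuse.bundle import TransitionMatrix

from conftest import brute_force_knn_adjacency


def _blobs(rng, n_per=30, d=10, sep=8.0):
    X = np.vstack([rng.normal(0, 1, (n_per, d)), rng.normal(sep, 1, (n_per, d))])
    labels = np.array([0] * n_per + [1] * n_per)
    return X, labels


def _ari(a, b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(a, b)


class TestBaselines:
    def test_unintegrated_graph_matches_dense_oracle(self, rng):
        X = rng.normal(size=(60, 12))
        res = integrate_unintegrated(X, k=10, n_pcs=12)
        oracle = brute_force_knn_adjacency(res.embedding.coordinates, 10)
        assert (res.graph.adjacency != oracle).nnz == 0

    def test_duplicate_cells_are_mutual_neighbors(self, rng):
        X = rng.normal(size=(20, 5))
        X[7] = X[3]
        res = integrate_unintegrated(X, k=3, n_pcs=5)
        A = res.graph.adjacency
        assert A[3, 7] == 1 and A[7, 3] == 1

    def test_fewer_features_than_components_is_fine(self, rng):
        X = rng.normal(size=(30, 7))
        res = integrate_unintegrated(X, k=5, n_pcs=50)
        assert res.embedding.K == 7

    def test_concat_with_zero_second_modality_equals_unintegrated(self, rng):
        X = rng.normal(size=(40, 6))
        a = integrate_concat(X, np.zeros_like(X), k=5)
        b = integrate_unintegrated(X, k=5)
        assert (a.graph.adjacency != b.graph.adjacency).nnz == 0

    def test_concat_duplicated_modality_keeps_neighbor_ranking(self, rng):
        X = rng.normal(size=(40, 6))
        a = integrate_concat(X, X.copy(), k=5)
        b = integrate_unintegrated(X, k=5)
        assert (a.graph.adjacency != b.graph.adjacency).nnz == 0

    def test_concat_shapes(self, rng):
        X1 = rng.normal(size=(50, 30))
        X2 = rng.normal(size=(50, 30))
        res = integrate_concat(X1, X2, n_pcs=60)
        assert res.embedding.K == min(60, 49)

    def test_sum_with_zero_equals_unintegrated(self, rng):
        X = rng.normal(size=(40, 6))
        a = integrate_sum(X, np.zeros_like(X), k=5)
        b = integrate_unintegrated(X, k=5)
        assert (a.graph.adjacency != b.graph.adjacency).nnz == 0

    def test_sum_cancellation_reports_degenerate_input(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(DegenerateInputError):
            integrate_sum(X, -X)

    def test_sum_matches_oracle_knn(self, rng):
        X1 = rng.normal(size=(50, 8))
        X2 = rng.normal(size=(50, 8))
        res = integrate_sum(X1, X2, k=10, n_pcs=8)
        oracle = brute_force_knn_adjacency(res.embedding.coordinates, 10)
        assert (res.graph.adjacency != oracle).nnz == 0


class TestVelocityTransition:
    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(30, 6))
        g = integrate_unintegrated(X, k=5, n_pcs=6).graph
        V = rng.normal(size=(30, 6))
        P = velocity_transition(g, X, V)
        np.testing.assert_allclose(P.P.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_velocity_rows_uniform(self, rng):
        X = rng.normal(size=(20, 4))
        g = integrate_unintegrated(X, k=4, n_pcs=4).graph
        P = velocity_transition(g, X, np.zeros_like(X))
        nbrs = g.adjacency[0].indices
        np.testing.assert_allclose(P.P[0, nbrs], 0.25, atol=1e-12)

    def test_parallel_displacement_gets_max_probability(self):
        """4 cells on axes: velocity pointing at one neighbor favors it."""
        Ms = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.1], [0.0, -1.0]])
        import scipy.sparse as sp

        from modalfuse.bundle import NeighborGraph

        adj = sp.csr_matrix(np.array([[0, 1, 1, 1]] * 1 + [[0, 0, 0, 0]] * 3))
        g = NeighborGraph(adj, k=3)
        V = np.zeros_like(Ms)
        V[0] = [1.0, 0.0]  # exactly toward cell 1
        P = velocity_transition(g, Ms, V, scheme="cosine")
        assert P.P[0].argmax() == 1

    @pytest.mark.parametrize("scheme", ["cosine", "correlation", "dot"])
    def test_all_schemes_stochastic(self, rng, scheme):
        X = rng.normal(size=(25, 5))
        g = integrate_unintegrated(X, k=5, n_pcs=5).graph
        P = velocity_transition(g, X, rng.normal(size=(25, 5)), scheme=scheme)
        np.testing.assert_allclose(P.P.sum(axis=1), 1.0, atol=1e-9)


class TestCellRank:
    def test_lambda_endpoints_exact(self, rng):
        X = rng.normal(size=(20, 5))
        g = integrate_unintegrated(X, k=5, n_pcs=5).graph
        P_s = expression_transition(g)
        P_v = velocity_transition(g, X, rng.normal(size=(20, 5)))
        assert np.array_equal(integrate_cellrank(P_s, P_v, 0.0, k=5).transition.P, P_s.P)
        assert np.array_equal(integrate_cellrank(P_s, P_v, 1.0, k=5).transition.P, P_v.P)

    def test_hand_arithmetic_two_by_two(self):
        P_s = TransitionMatrix(np.array([[0.9, 0.1], [0.2, 0.8]]))
        P_v = TransitionMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
        res = integrate_cellrank(P_s, P_v, 0.5, k=1)
        np.testing.assert_allclose(res.transition.P, [[0.7, 0.3], [0.35, 0.65]], atol=1e-12)

    def test_lambda_out_of_range_rejected(self):
        P = TransitionMatrix(np.eye(2))
        with pytest.raises(ValueError, match="lam"):
            integrate_cellrank(P, P, 1.5)


class TestSNF:
    def test_laplacian_has_zero_eigenvalue_with_constant_eigenvector(self, rng):
        X, _ = _blobs(rng, n_per=25, sep=3.0)
        res = integrate_snf(X, X + rng.normal(0, 0.1, X.shape), k=10, K_eigs=5)
        A = res.extras["fused_affinity"]
        L = np.diag(A.sum(1)) - A
        vals, vecs = scipy.linalg.eigh(L)
        assert abs(vals[0]) < 1e-8
        v0 = vecs[:, 0]
        assert np.allclose(v0, v0.mean(), atol=1e-6)

    def test_identical_modalities_recover_blob_structure(self, rng):
        """Spectral clustering on the fused embedding separates two blobs."""
        from sklearn.cluster import KMeans

        X, labels = _blobs(rng)
        res = integrate_snf(X, X.copy(), k=10, K_eigs=2)
        E = res.embedding.coordinates
        E = E / np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        pred = KMeans(2, n_init=10, random_state=0).fit_predict(E)
        assert _ari(labels, pred) == 1.0

    def test_embedding_eigenvectors_orthonormal(self, rng):
        X, _ = _blobs(rng, n_per=20)
        res = integrate_snf(X, X, k=8, K_eigs=6)
        E = res.embedding.coordinates
        np.testing.assert_allclose(E.T @ E, np.eye(6), atol=1e-8)

    def test_k_eigs_bounded(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="K_eigs"):
            integrate_snf(X, X, K_eigs=10)


class TestGrassmann:
    def test_alpha_zero_reduces_to_laplacian_sum(self, rng):
        X1 = rng.normal(size=(30, 6))
        X2 = rng.normal(size=(30, 6))
        res = integrate_grassmann(X1, X2, k=8, alpha=0.0, K_eigs=5)
        Ls = res.extras["modality_laplacians"]
        np.testing.assert_allclose(res.extras["L_mod"], Ls[0] + Ls[1], atol=1e-12)

    def test_normalized_laplacian_eigenvalues_in_unit_band(self, rng):
        X = rng.normal(size=(40, 8))
        res = integrate_grassmann(X, X, k=10, K_eigs=5)
        for L in res.extras["modality_laplacians"]:
            vals = scipy.linalg.eigvalsh(L)
            assert vals.min() > -1e-9 and vals.max() < 2.0 + 1e-9

    def test_identical_modalities_recover_blob_structure(self, rng):
        from sklearn.cluster import KMeans

        X, labels = _blobs(rng)
        res = integrate_grassmann(X, X.copy(), k=10, K_eigs=3)
        pred = KMeans(2, n_init=10, random_state=0).fit_predict(res.embedding.coordinates)
        assert _ari(labels, pred) == 1.0


class TestIntegratedDiffusion:
    def test_joint_operator_rows_sum_to_one(self, rng):
        X, _ = _blobs(rng, n_per=20)
        res = integrate_integrated_diffusion(X, X + rng.normal(0, 0.2, X.shape), n_clusters=2, k=8, K_eigs=4)
        np.testing.assert_allclose(res.transition.P.sum(axis=1), 1.0, atol=1e-9)

    def test_spectral_entropy_non_increasing_in_time(self, rng):
        lam = rng.uniform(0, 1, 30)
        lam[0] = 1.0
        H = [spectral_entropy(lam, t) for t in range(1, 11)]
        assert all(H[i] >= H[i + 1] - 1e-12 for i in range(9))

    def test_identical_modalities_unit_times_square_operator(self, rng):
        """With equal operators and t1=t2=1, P_j before its own powering is P^2."""
        from modalfuse.integrate import _diffusion_operator

        X, _ = _blobs(rng, n_per=15)
        P = _diffusion_operator(X, 8)
        P_j = P @ P
        np.testing.assert_allclose(P_j.sum(axis=1), 1.0, atol=1e-9)


class TestPrecise:
    def test_identical_modalities_give_unit_cosines(self, rng):
        X = rng.normal(size=(40, 12))
        res = integrate_precise(X, X.copy(), n_pv=6)
        np.testing.assert_allclose(res.extras["cosines"], 1.0, atol=1e-9)

    def test_cosines_non_increasing(self, rng):
        X1 = rng.normal(size=(50, 10))
        X2 = rng.normal(size=(50, 10))
        res = integrate_precise(X1, X2, n_pv=8)
        assert (np.diff(res.extras["cosines"]) <= 1e-12).all()

    def test_principal_vectors_orthonormal_and_projection_matches_oracle(self, rng):
        X1 = rng.normal(size=(50, 10))
        X2 = rng.normal(size=(50, 10))
        res = integrate_precise(X1, X2, n_pv=5)
        Q1 = res.extras["pv_1"]
        np.testing.assert_allclose(Q1.T @ Q1, np.eye(5), atol=1e-8)
        oracle = (X1 - X1.mean(0)) @ Q1
        np.testing.assert_allclose(res.embedding.coordinates, oracle, atol=1e-10)

    def test_consensus_mode_midpoint_projection(self, rng):
        X1 = rng.normal(size=(30, 8))
        res = integrate_precise(X1, X1 + rng.normal(0, 0.1, X1.shape), n_pv=4, mode="consensus")
        assert res.embedding.coordinates.shape == (30, 4)


class TestWNN:
    def test_weights_sum_to_one(self, rng):
        X1 = rng.normal(size=(40, 8))
        X2 = rng.normal(size=(40, 8))
        res = integrate_wnn(X1, X2, k=5, n_pcs=8)
        np.testing.assert_allclose(res.extras["modality_weights"].sum(axis=1), 1.0, atol=1e-12)

    def test_identical_modalities_weighted_evenly(self, rng):
        X = rng.normal(size=(60, 10))
        res = integrate_wnn(X, X.copy(), k=5, n_pcs=10)
        w1 = res.extras["modality_weights"][:, 0]
        assert abs(np.median(w1) - 0.5) < 0.05

    def test_structured_modality_outweighs_noise(self):
        """Blobs in X1, pure noise in X2: X1 dominates and the joint graph
        keeps the blob structure at least as well as the noise-only graph."""
        from sklearn.cluster import KMeans

        med_w1, ari_joint, ari_noise = [], [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X1, labels = _blobs(rng, n_per=25, sep=6.0)
            X2 = rng.normal(size=X1.shape)
            res = integrate_wnn(X1, X2, k=5, n_pcs=10)
            med_w1.append(np.median(res.extras["modality_weights"][:, 0]))
            for store, X in ((ari_joint, None), (ari_noise, X2)):
                if X is None:
                    emb = res.extras["joint_similarity"]
                    pred = KMeans(2, n_init=10, random_state=0).fit_predict(emb)
                else:
                    pred = KMeans(2, n_init=10, random_state=0).fit_predict(pca_embed(X, 10))
                store.append(_ari(labels, pred))
        assert np.median(med_w1) > 0.5
        assert np.median(ari_joint) >= np.median(ari_noise)


class TestFactorModel:
    def test_noiseless_generative_recovery(self, rng):
        Z = rng.normal(size=(300, 5))
        W1 = rng.normal(size=(40, 5))
        W2 = rng.normal(size=(40, 5))
        X1, X2 = Z @ W1.T, Z @ W2.T
        res = integrate_factor_model(X1, X2, K=5, max_iter=500)
        model = res.extras["model"]
        err = np.linalg.norm(X1 - model.Z @ model.W1.T) / np.linalg.norm(X1)
        assert err < 1e-6

    def test_objective_monotone_non_increasing(self, rng):
        X1 = rng.normal(size=(60, 20))
        X2 = rng.normal(size=(60, 20))
        res = integrate_factor_model(X1, X2, K=8, max_iter=50)
        obj = res.extras["model"].objective
        assert (np.diff(obj) <= 1e-8 * obj[0]).all()

    def test_rank_one_recovers_leading_singular_direction(self, rng):
        u = rng.normal(size=(80, 1))
        v = rng.normal(size=(15, 1))
        X = u @ v.T
        res = integrate_factor_model(X, X.copy(), K=1, max_iter=300)
        z = res.extras["model"].Z[:, 0]
        cos = abs(z @ u[:, 0]) / (np.linalg.norm(z) * np.linalg.norm(u))
        assert cos > 0.999

    def test_k_larger_than_dims_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="K="):
            integrate_factor_model(X, X, K=8)


class TestRegistryContracts:
    @pytest.mark.parametrize(
        "name", [m for m in METHODS if m not in ("unintegrated", "cellrank")]
    )
    def test_every_method_emits_aligned_k10_graph(self, rng, name):
        X1 = rng.normal(size=(60, 15))
        X2 = rng.normal(size=(60, 15))
        kwargs = {"K": 5} if name == "factor" else {}
        res = run_method(name, X1, X2, **kwargs)
        A = res.graph.adjacency
        assert A.shape == (60, 60)
        counts = np.diff(A.indptr)
        assert counts.min() >= 1 and counts.max() <= max(res.graph.k, 59)
        assert A.diagonal().sum() == 0

    def test_cellrank_via_registry(self, rng):
        Ms = rng.normal(size=(40, 8))
        V = rng.normal(size=(40, 8))
        res = run_method("cellrank", Ms, V, lam=0.3)
        np.testing.assert_allclose(res.transition.P.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(KeyError, match="unknown method"):
            run_method("magic", np.ones((3, 3)))
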