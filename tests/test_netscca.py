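import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netprofiler.exceptions import InvalidParameterError
from netprofiler.netscca import (
    NetSCCA,
    a_step,
    common_components_unpenalized,
    fusion_laplacian,
    gram_matrix,
    jaccard_similarity,
    neighbor_sets_from_network,
    netscca_fit,
    theta_step,
)
from netprofiler.simulate import simulate_common_structure, recovery_metrics

from oracles import lasso_subgradient_gap


class TestJaccardSimilarity:
    def test_identical_sets_are_one(self):
        sim = jaccard_similarity([{"a", "b"}, {"a", "b"}])
        assert sim.W[0, 1] == pytest.approx(1.0)

    def test_disjoint_sets_are_zero(self):
        sim = jaccard_similarity([{"a"}, {"b"}])
        assert sim.W[0, 1] == 0.0

    def test_enumerated_overlap(self):
        sim = jaccard_similarity([{"a", "b", "c"}, {"b", "c", "d"}])
        assert sim.W[0, 1] == pytest.approx(0.5)

    def test_two_empty_sets_are_zero(self):
        sim = jaccard_similarity([set(), set()])
        assert sim.W[0, 1] == 0.0
        assert sim.W[0, 0] == 0.0

    def test_symmetric(self):
        sim = jaccard_similarity([{"a"}, {"a", "b"}, {"c"}])
        np.testing.assert_allclose(sim.W, sim.W.T)

    def test_neighbor_sets_from_network_union_over_samples(self, small_panel):
        from netprofiler.network import fit_sample_specific_network, PenaltySpec

        panel, modulators, _ = small_panel
        net = fit_sample_specific_network(
            panel, modulators, penalty=PenaltySpec(lam=30.0)
        )
        sets = neighbor_sets_from_network(net)
        any_edge = np.any(net.coefficients != 0, axis=0)
        for j, s in enumerate(sets):
            expected = {net.target_ids[l] for l in np.nonzero(any_edge[j])[0]}
            assert s == expected


class TestGramMatrix:
    def test_orthonormal_single_matrix_gives_identity(self):
        R = np.linalg.qr(np.random.default_rng(0).standard_normal((8, 4)))[0]
        gf = gram_matrix([R])
        np.testing.assert_allclose(gf.G, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(gf.Q, np.eye(4), atol=1e-8)

    def test_square_root_reconstructs_gram(self, rng):
        mats = [rng.standard_normal((20, 6)) for _ in range(4)]
        gf = gram_matrix(mats)
        rel = np.linalg.norm(gf.Q @ gf.Q - gf.G) / np.linalg.norm(gf.G)
        assert rel < 1e-8

    def test_gram_is_psd(self, rng):
        mats = [rng.standard_normal((15, 5)) for _ in range(3)]
        gf = gram_matrix(mats)
        assert np.all(np.linalg.eigvalsh(gf.G) >= -1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidParameterError):
            gram_matrix([np.array([[np.nan, 1.0]])])


class TestUnpenalizedComponents:
    def test_diagonal_case_by_hand(self):
        A = common_components_unpenalized(np.diag([4.0, 2.0, 1.0]), 1)
        np.testing.assert_allclose(np.abs(A[:, 0]), [1, 0, 0], atol=1e-12)

    def test_beats_random_orthonormal_candidates(self, rng):
        G = gram_matrix([rng.standard_normal((30, 8)) for _ in range(2)]).G
        A = common_components_unpenalized(G, 3)
        best = np.trace(A.T @ G @ A)
        for _ in range(100):
            Q, _ = np.linalg.qr(rng.standard_normal((8, 3)))
            assert np.trace(Q.T @ G @ Q) <= best + 1e-9

    def test_full_basis_gives_total_trace(self, rng):
        G = gram_matrix([rng.standard_normal((10, 4))]).G
        A = common_components_unpenalized(G, 4)
        assert np.trace(A.T @ G @ A) == pytest.approx(np.trace(G))

    def test_k_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            common_components_unpenalized(np.eye(3), 4)


class TestThetaStep:
    def test_unpenalized_is_least_squares(self, rng):
        Q = rng.standard_normal((10, 4))
        z = rng.standard_normal(10)
        theta = theta_step(Q, z, None, 0.0, 0.0)
        expected, *_ = np.linalg.lstsq(Q, z, rcond=None)
        np.testing.assert_allclose(theta, expected, atol=1e-8)

    def test_lambda2_zero_matches_lasso_oracle(self, rng):
        """Without the fusion term the theta step is a lasso; compare with
        sklearn on the equivalent least-squares problem."""
        from sklearn.linear_model import Lasso

        for seed in range(5):
            g = np.random.default_rng(seed)
            Q = g.standard_normal((12, 5))
            z = g.standard_normal(12)
            lam1 = 0.8
            theta = theta_step(Q, z, None, lam1, 0.0)
            # ||z - Q t||^2 + lam1 ||t||_1 == 2n * (1/(2n)||..||^2 + (lam1/(2n))||t||_1)
            sk = Lasso(alpha=lam1 / (2 * len(z)), fit_intercept=False,
                       tol=1e-14, max_iter=10_000_00).fit(Q, z)
            np.testing.assert_allclose(theta, sk.coef_, atol=1e-7)

    def test_subgradient_conditions(self, rng):
        for seed in range(10):
            g = np.random.default_rng(seed)
            p = 5
            Q = g.standard_normal((9, p))
            z = g.standard_normal(9)
            W = np.abs(g.uniform(size=(p, p)))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 1.0)
            W = np.clip(W, 0, 1)
            lam1, lam2 = 0.5, 0.7
            theta = theta_step(Q, z, W, lam1, lam2)
            M = Q.T @ Q + lam2 * fusion_laplacian(W)
            assert lasso_subgradient_gap(M, Q.T @ z, theta, lam1) < 1e-6

    def test_ridge_laplacian_closed_form_at_lambda1_zero(self, rng):
        p = 5
        Q = rng.standard_normal((10, p))
        z = rng.standard_normal(10)
        W = np.full((p, p), 0.5)
        np.fill_diagonal(W, 1.0)
        lam2 = 1.3
        theta = theta_step(Q, z, W, 0.0, lam2)
        L = fusion_laplacian(W)
        expected = np.linalg.solve(Q.T @ Q + lam2 * L, Q.T @ z)
        np.testing.assert_allclose(theta, expected, atol=1e-8)

    def test_large_fusion_pulls_connected_coefficients_together(self):
        rng = np.random.default_rng(4)
        Q = rng.standard_normal((20, 4))
        z = Q @ np.array([2.0, -1.0, 0.5, 0.0]) + 0.1 * rng.standard_normal(20)
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        base = theta_step(Q, z, W, 0.0, 0.0)
        fused = theta_step(Q, z, W, 0.0, 100.0)
        assert abs(fused[0] - fused[1]) < abs(base[0] - base[1])
        # brute-force quadratic solve agrees
        L = fusion_laplacian(W)
        expected = np.linalg.solve(Q.T @ Q + 100.0 * L, Q.T @ z)
        np.testing.assert_allclose(fused, expected, atol=1e-8)


class TestAStep:
    def test_identity_gram_returns_theta(self):
        Theta, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((6, 2)))
        A = a_step(np.eye(6), Theta)
        np.testing.assert_allclose(A, Theta, atol=1e-10)

    def test_procrustes_optimality(self, rng):
        Q = rng.standard_normal((12, 6))
        Theta = rng.standard_normal((6, 2))
        A = a_step(Q, Theta)
        np.testing.assert_allclose(A.T @ A, np.eye(2), atol=1e-8)
        M = Q.T @ Q @ Theta
        best = np.trace(A.T @ M)
        for _ in range(100):
            C, _ = np.linalg.qr(rng.standard_normal((6, 2)))
            assert np.trace(C.T @ M) <= best + 1e-9

    def test_sign_equivariance(self, rng):
        Q = rng.standard_normal((10, 4))
        Theta = rng.standard_normal((4, 2))
        A = a_step(Q, Theta)
        Theta2 = Theta.copy()
        Theta2[:, 1] *= -1
        A2 = a_step(Q, Theta2)
        np.testing.assert_allclose(A2[:, 1], -A[:, 1], atol=1e-10)
        np.testing.assert_allclose(A2[:, 0], A[:, 0], atol=1e-10)


class TestNetsccaFit:
    def test_single_matrix_unpenalized_is_standard_pca(self, rng):
        R = rng.standard_normal((40, 8))
        model = netscca_fit([R], K=3, lambda1=0.0, lambda2=0.0)
        _, _, Vt = np.linalg.svd(R, full_matrices=False)
        for k in range(3):
            cos = abs(model.loadings[:, k] @ Vt[k])
            assert cos >= 1 - 1e-6

    def test_huge_lambda1_zeroes_all_loadings(self, rng):
        R = rng.standard_normal((20, 5))
        with pytest.warns(RuntimeWarning):
            model = netscca_fit([R], K=2, lambda1=1e9, lambda2=0.0, max_iter=5)
        assert model.zero_components == [0, 1]
        assert np.all(model.loadings == 0)

    def test_recovers_shared_sparse_loading(self):
        f1s, coss = [], []
        for seed in range(3):
            eff, V, nsets = simulate_common_structure(
                q=5, n=200, p=50, K=1, support_size=10, noise_sd=0.1, seed=seed
            )
            model = netscca_fit(
                eff, W=jaccard_similarity(nsets), K=1, lambda1=2.0, lambda2=1.0
            )
            met = recovery_metrics(
                true_support=V[:, 0] != 0,
                est_support=model.loadings[:, 0] != 0,
                true_loading=V[:, 0],
                est_loading=model.loadings[:, 0],
            )
            f1s.append(met["f1"])
            coss.append(met["abs_cosine"])
        assert np.mean(f1s) >= 0.8
        assert np.mean(coss) >= 0.9

    def test_objective_non_increasing_unpenalized(self, rng):
        mats = [rng.standard_normal((25, 10)) for _ in range(3)]
        model = netscca_fit(mats, K=2, lambda1=0.0, lambda2=0.0, tol=1e-12,
                            max_iter=50)
        obj = model.objective_trace
        assert all(b <= a + 1e-8 for a, b in zip(obj, obj[1:]))

    def test_loading_columns_unit_norm_and_sign_convention(self, rng):
        mats = [rng.standard_normal((20, 6)) for _ in range(2)]
        model = netscca_fit(mats, K=2, lambda1=0.5)
        for k in range(2):
            col = model.loadings[:, k]
            assert np.linalg.norm(col) == pytest.approx(1.0)
            assert col[np.argmax(np.abs(col))] > 0

    def test_auto_K_explains_80_percent(self, rng):
        # one dominant direction -> K = 1
        v = rng.standard_normal(6)
        v /= np.linalg.norm(v)
        R = np.outer(rng.standard_normal(50), v)
        R += 0.01 * rng.standard_normal(R.shape)
        model = netscca_fit([R])
        assert model.K == 1

    def test_estimator_wrapper(self, rng):
        mats = [rng.standard_normal((15, 5)) for _ in range(2)]
        est = NetSCCA(n_components=2).fit(mats)
        assert est.components_.shape == (2, 5)
        proj = est.transform(mats[0])
        assert proj.shape == (15, 2)
        np.testing.assert_allclose(proj, mats[0] @ est.components_.T)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_fusion_penalty_equals_laplacian_quadratic_form(seed):
    rng = np.random.default_rng(seed)
    p = 6
    W = rng.uniform(size=(p, p))
    W = (W + W.T) / 2
    theta = rng.standard_normal(p)
    L = fusion_laplacian(W)
    direct = sum(
        (theta[j] - theta[s]) ** 2 * W[j, s]
        for j in range(p)
        for s in range(j + 1, p)
    )
    assert abs(theta @ L @ theta - direct) < 1e-10


def test_similarity_invariant_under_sample_permutation(small_panel):
    """W is built from which edges exist in at least one sample, so
    permuting sample order cannot change it."""
    from netprofiler.network import fit_sample_specific_network, PenaltySpec

    panel, modulators, _ = small_panel
    net = fit_sample_specific_network(
        panel, modulators, penalty=PenaltySpec(lam=30.0)
    )
    sets1 = neighbor_sets_from_network(net)
    perm = np.random.default_rng(0).permutation(panel.n_samples)
    net.coefficients = net.coefficients[perm]
    sets2 = neighbor_sets_from_network(net)
    np.testing.assert_allclose(
        jaccard_similarity(sets1).W, jaccard_similarity(sets2).W
    )
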