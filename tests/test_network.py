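import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netprofiler as npf
from netprofiler.exceptions import (
    DegenerateWeightsError,
    InvalidParameterError,
)
from netprofiler.kernels import KernelConfig
from netprofiler.network import (
    NetworkProfiler,
    PenaltySpec,
    default_lambda_grid,
    fit_penalized_regression,
    fit_sample_specific_network,
    select_lambda,
    variance_filter,
)
from netprofiler.simulate import simulate_varying_network

from oracles import cd_oracle, weighted_sd


def _random_instance(seed, n=25, p=4, weighted=True):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.choice([0.0, 1.0, -2.0], size=p)
    y = X @ beta + 0.5 * rng.standard_normal(n)
    w = rng.uniform(0.1, 2.0, size=n) if weighted else np.ones(n)
    return X, y, w


class TestPenalizedRegression:
    def test_huge_lambda_zeroes_all_coefficients(self):
        X, y, w = _random_instance(0)
        fit = fit_penalized_regression(
            X, y, PenaltySpec(lam=1e9), weights=w
        )
        assert np.all(fit.coef == 0)
        # intercept is the weighted mean of y
        assert fit.intercept == pytest.approx(float(w @ y / w.sum()))

    def test_zero_lambda_is_weighted_least_squares(self):
        X, y, w = _random_instance(1, n=40, p=3)
        fit = fit_penalized_regression(
            X, y, PenaltySpec(lam=0.0), weights=w, tol=1e-12
        )
        Xa = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.solve(Xa.T @ (w[:, None] * Xa), Xa.T @ (w * y))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(fit.coef, beta[1:], atol=1e-8)

    @pytest.mark.parametrize("family,gamma", [("lasso", None),
                                              ("elastic_net", 0.3),
                                              ("ridge", None)])
    def test_matches_naive_coordinate_descent_oracle(self, family, gamma):
        """Weighted fits agree with an independent raw-scale CD oracle that
        emulates the internal standardization via per-feature penalties."""
        for seed in range(10):
            X, y, w = _random_instance(seed)
            lam = 0.5 + seed * 0.3
            spec = PenaltySpec(family=family, lam=lam, gamma=gamma)
            fit = fit_penalized_regression(X, y, spec, weights=w, tol=1e-13)
            l1, l2 = spec.l1_l2(lam)
            s = weighted_sd(X, w)
            beta, b0 = cd_oracle(
                X, y, w, l1, l2, l1_per_feature=l1 * s, l2_per_feature=l2 * s**2
            )
            np.testing.assert_allclose(fit.coef, beta, atol=1e-8)
            assert fit.intercept == pytest.approx(b0, abs=1e-8)

    def test_uniform_weights_match_sklearn_lasso(self):
        """Unstandardized uniform-weight fits reproduce the standard lasso
        (sklearn objective 1/(2n)||y-Xb||^2 + alpha||b||_1 maps to
        lam = alpha * n)."""
        from sklearn.linear_model import Lasso

        for seed in range(5):
            X, y, _ = _random_instance(seed, n=30, p=5, weighted=False)
            lam = 3.0
            fit = fit_penalized_regression(
                X, y, PenaltySpec(lam=lam), standardize=False, tol=1e-13
            )
            sk = Lasso(alpha=lam / len(y), tol=1e-12, max_iter=500_000).fit(X, y)
            np.testing.assert_allclose(fit.coef, sk.coef_, atol=1e-7)
            assert fit.intercept == pytest.approx(sk.intercept_, abs=1e-7)

    def test_degenerate_weights_rejected(self):
        X, y, _ = _random_instance(2)
        with pytest.raises(DegenerateWeightsError):
            fit_penalized_regression(X, y, weights=np.zeros(len(y)))
        w = np.zeros(len(y))
        w[0] = 1.0
        with pytest.raises(DegenerateWeightsError):
            fit_penalized_regression(X, y, weights=w)

    def test_constant_response_returns_intercept_only(self):
        X, _, w = _random_instance(3)
        y = np.full(X.shape[0], 4.2)
        with pytest.warns(RuntimeWarning):
            fit = fit_penalized_regression(X, y, PenaltySpec(lam=1.0), weights=w)
        assert np.all(fit.coef == 0)
        assert fit.intercept == pytest.approx(4.2)

    def test_weight_lambda_equivariance(self):
        """Scaling all weights by c and lambda by c leaves the fit unchanged."""
        X, y, w = _random_instance(4)
        lam, c = 1.5, 7.0
        fit1 = fit_penalized_regression(
            X, y, PenaltySpec(lam=lam), weights=w, tol=1e-13
        )
        fit2 = fit_penalized_regression(
            X, y, PenaltySpec(lam=c * lam), weights=c * w, tol=1e-13
        )
        np.testing.assert_allclose(fit1.coef, fit2.coef, atol=1e-9)

    def test_sparsity_monotone_in_lambda(self):
        X, y, w = _random_instance(5, n=30, p=4)
        grid = default_lambda_grid(X, y, w, n_points=15)
        nnz = [
            np.count_nonzero(
                fit_penalized_regression(
                    X, y, PenaltySpec(lam=float(lam)), weights=w
                ).coef
            )
            for lam in np.sort(grid)[::-1]
        ]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))


class TestSelectLambda:
    def test_singleton_grid_returned(self):
        X, y, w = _random_instance(0)
        spec = PenaltySpec(lambda_grid=np.array([0.7]))
        assert select_lambda(X, y, w, spec) == pytest.approx(0.7)

    def test_empty_grid_rejected(self):
        X, y, w = _random_instance(0)
        with pytest.raises(InvalidParameterError):
            select_lambda(X, y, w, PenaltySpec(lambda_grid=np.array([])))

    def test_pure_noise_selects_near_empty_model(self):
        """Under a null design the selected model is (near) empty in at
        least 90% of seeded replicates."""
        near_empty = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 5))
            y = rng.standard_normal(200)
            lam = select_lambda(X, y)
            fit = fit_penalized_regression(X, y, PenaltySpec(lam=lam))
            near_empty += np.count_nonzero(fit.coef) <= 1
        assert near_empty >= 45

    def test_strong_signal_predictor_selected(self):
        included = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((100, 5))
            y = 2.0 * X[:, 2] + 0.5 * rng.standard_normal(100)
            lam = select_lambda(X, y)
            fit = fit_penalized_regression(X, y, PenaltySpec(lam=lam))
            included += fit.coef[2] != 0
        assert included >= 48

    def test_weighted_cv_is_deterministic(self):
        X, y, w = _random_instance(6, n=40)
        spec = PenaltySpec(selection="weighted_cv")
        assert select_lambda(X, y, w, spec, seed=3) == select_lambda(
            X, y, w, spec, seed=3
        )


class TestVarianceFilter:
    def test_identity_filter(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 7))
        np.testing.assert_array_equal(variance_filter(X, 1.0), np.arange(7))

    def test_quantile_enumeration(self):
        # columns with sample variances exactly 1..10
        base = np.array([-1.0, 1.0]) / np.sqrt(2)  # ddof=1 variance 1
        X = np.column_stack([np.sqrt(v) * base for v in range(1, 11)])
        np.testing.assert_array_equal(variance_filter(X, 0.2), [8, 9])
        np.testing.assert_array_equal(variance_filter(X, 0.1), [9])

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 5))
        X[:, 2] = 3.0
        assert 2 not in variance_filter(X, 0.8)

    def test_ties_broken_by_gene_order(self):
        X = np.tile(np.array([[-1.0], [1.0]]), (1, 4))
        np.testing.assert_array_equal(variance_filter(X, 0.5), [0, 1])


class TestSampleSpecificNetwork:
    def test_infinite_bandwidth_equals_pooled_regression(self, small_panel):
        panel, modulators, _ = small_panel
        net = fit_sample_specific_network(
            panel, modulators,
            KernelConfig(mode="constant", bandwidth=1e12),
            PenaltySpec(lam=5.0),
        )
        pooled = fit_penalized_regression(
            panel.X, panel.Y[:, 0], PenaltySpec(lam=5.0)
        )
        for a in range(panel.n_samples):
            np.testing.assert_allclose(
                net.coefficients[a, :, 0], pooled.coef, atol=1e-8
            )

    def test_linear_edge_tracks_modulator(self):
        """A single edge with coefficient 2m is recovered with a
        coefficient profile strongly correlated with m."""
        from netprofiler.simulate import SimulationTruth

        truth = SimulationTruth(
            beta=lambda j, l, m: 2.0 * m if j == 0 else 0.0,
            noise_sd=0.2,
            seed=11,
        )
        panel, modulators, _ = simulate_varying_network(
            n=300, p=10, q=1, truth=truth, seed=11
        )
        net = fit_sample_specific_network(panel, modulators)
        r = np.corrcoef(net.coefficients[:, 0, 0], modulators.column())[0, 1]
        assert r >= 0.9

    def test_threshold_edge_support_matches_truth(self):
        """An edge that vanishes above a modulator cutoff is detected below
        and absent above the cutoff for most samples."""
        from netprofiler.simulate import SimulationTruth

        truth = SimulationTruth(
            beta=lambda j, l, m: (2.0 if m <= 6.0 else 0.0) if j == 0 else 0.0,
            noise_sd=0.5,
            seed=5,
        )
        panel, modulators, _ = simulate_varying_network(
            n=250, p=6, q=1, truth=truth, seed=5
        )
        net = fit_sample_specific_network(panel, modulators)
        m = modulators.column()
        est = net.coefficients[:, 0, 0] != 0
        true = m <= 6.0
        tp = np.count_nonzero(est & true)
        precision = tp / max(np.count_nonzero(est), 1)
        recall = tp / np.count_nonzero(true)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.8

    def test_self_loop_excluded_when_gene_is_regulator_and_target(self, rng):
        from netprofiler.data import ExpressionPanel, ModulatorTable

        n = 40
        X = rng.standard_normal((n, 3))
        panel = ExpressionPanel(
            X, X.copy(), ["G0", "G1", "G2"], ["G0", "G1", "G2"],
            [f"S{i}" for i in range(n)],
        )
        mods = ModulatorTable(
            rng.normal(size=(n, 1)), panel.sample_ids, ["m"]
        )
        net = fit_sample_specific_network(
            panel, mods, penalty=PenaltySpec(lam=1.0)
        )
        for g in range(3):
            assert np.all(net.coefficients[:, g, g] == 0)

    def test_multivariate_h1_matches_constant_kernel(self, small_panel):
        """With one characteristic and H = (b), the multivariate kernel fit
        equals a constant-bandwidth fit at 2b (the determinant prefactor
        cancels in the per-fit weight rescaling)."""
        panel, modulators, _ = small_panel
        b = 2.0
        net_mv = fit_sample_specific_network(
            panel, modulators,
            KernelConfig(mode="multivariate", bandwidth_matrix=np.array([[b]])),
            PenaltySpec(lam=20.0),
        )
        net_c = fit_sample_specific_network(
            panel, modulators,
            KernelConfig(mode="constant", bandwidth=2 * b),
            PenaltySpec(lam=20.0),
        )
        np.testing.assert_allclose(
            net_mv.coefficients, net_c.coefficients, atol=1e-8
        )

    def test_mse_decreases_with_sample_size(self):
        """Coefficient error of the fitted networks shrinks as n grows."""
        errors = {}
        for n in (100, 400):
            mses = []
            for seed in range(3):
                panel, modulators, truth = simulate_varying_network(
                    n=n, p=5, q=2, seed=seed
                )
                net = fit_sample_specific_network(panel, modulators)
                B = truth.coefficient_tensor(modulators.column(), 5, 2)
                mses.append(float(np.mean((net.coefficients - B) ** 2)))
            errors[n] = np.mean(mses)
        assert errors[400] < errors[100]

    def test_threads_do_not_change_results(self, small_panel):
        panel, modulators, _ = small_panel
        net1 = fit_sample_specific_network(
            panel, modulators, penalty=PenaltySpec(lam=10.0), threads=1
        )
        net2 = fit_sample_specific_network(
            panel, modulators, penalty=PenaltySpec(lam=10.0), threads=2
        )
        np.testing.assert_array_equal(net1.coefficients, net2.coefficients)

    def test_diagnostics_record_effective_size_and_lambda(self, small_panel):
        panel, modulators, _ = small_panel
        net = fit_sample_specific_network(
            panel, modulators, penalty=PenaltySpec(lam=10.0)
        )
        diag = net.diagnostics
        assert len(diag) == panel.n_samples * panel.n_targets
        assert (diag["effective_size"] > 0).all()
        assert (diag["lambda"] == 10.0).all()


class TestNetworkProfilerEstimator:
    def test_sklearn_params_roundtrip(self):
        est = NetworkProfiler(k=7, reg_lambda=2.0)
        params = est.get_params()
        assert params["k"] == 7
        est2 = NetworkProfiler().set_params(**params)
        assert est2.get_params() == params

    def test_fit_sets_fitted_attributes(self, small_panel):
        panel, modulators, _ = small_panel
        est = NetworkProfiler(reg_lambda=10.0).fit(panel, modulators=modulators)
        assert est.coef_.shape == (80, 5, 2)
        assert est.intercept_.shape == (80, 2)
        assert est.network_.sample_ids == panel.sample_ids

    def test_fit_accepts_plain_arrays(self, rng):
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 2))
        m = rng.normal(size=30)
        est = NetworkProfiler(reg_lambda=5.0).fit(X, Y, modulators=m)
        assert est.coef_.shape == (30, 4, 2)

    def test_modulators_required(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(InvalidParameterError):
            NetworkProfiler().fit(X, X[:, :1])


@settings(derandomize=True, max_examples=15, deadline=None)
@given(seed=st.integers(0, 1000), lam=st.floats(0.1, 50.0))
def test_cd_solution_satisfies_kkt(seed, lam):
    """Every lasso fit satisfies the subgradient optimality conditions of
    its weighted objective."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((30, 4))
    y = rng.standard_normal(30)
    w = rng.uniform(0.2, 2.0, 30)
    fit = fit_penalized_regression(
        X, y, PenaltySpec(lam=lam), weights=w, standardize=False, tol=1e-13
    )
    resid = y - fit.intercept - X @ fit.coef
    grad = -(w * resid) @ X
    for j in range(4):
        if fit.coef[j] != 0:
            assert abs(grad[j] + lam * np.sign(fit.coef[j])) < 1e-6
        else:
            assert abs(grad[j]) <= lam + 1e-6
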