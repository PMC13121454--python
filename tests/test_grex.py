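import numpy as np
import pytest
from sklearn.base import clone

from sctwas import CountGReXRegressor
from sctwas.data import NotModelableError, SctwasError
from sctwas.grex import (
    compute_weights,
    estimate_null_overdispersion,
    evaluate_prediction_cv,
    fit_weighted_elastic_net,
    irls_fit,
    predict_grex,
    select_lambda_cv,
    weighted_enet_objective,
)
from sctwas.simulate import SimulationConfig, simulate_expression_counts, simulate_genotypes


class TestWeights:
    def test_hand_value(self):
        # s=100, mu=0.01, theta=10: Var = 1 + 0.1 = 1.1
        w = compute_weights(np.array([0.01]), np.array([100.0]), 10.0)
        assert w[0] == pytest.approx(1 / 1.1, rel=1e-12)

    def test_poisson_limit(self, rng):
        mu = rng.uniform(0.001, 0.1, 50)
        s = rng.uniform(100, 1000, 50)
        w = compute_weights(mu, s, 1e12)
        assert np.allclose(w, 1 / (s * mu), rtol=1e-6)

    def test_zero_mu_floored_finite(self):
        w = compute_weights(np.array([0.0, -1.0]), np.array([100.0, 100.0]), 10.0)
        assert np.all(np.isfinite(w)) and np.all(w > 0)


class TestNullOverdispersion:
    def test_method_of_moments_hand_value(self):
        # strongly overdispersed toy so the moment denominator is positive
        x = np.array([2.0, 30.0, 1.0, 25.0, 3.0, 40.0, 2.0, 28.0, 5.0, 33.0])
        s = np.full(10, 100.0)
        mu0 = x.sum() / s.sum()                  # intercept-only null mean
        num = np.sum((s * mu0) ** 2)
        den = np.sum((x - s * mu0) ** 2 - s * mu0)
        assert den > 0
        expected = num / den
        theta, w, mu_hat = estimate_null_overdispersion(x, s)
        assert np.allclose(mu_hat, mu0)
        assert theta == pytest.approx(min(max(expected, 1e-2), 1e6), rel=1e-10)

    def test_poisson_data_theta_huge(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(500, 2000, 2000)
        x = rng.poisson(s * 0.05).astype(float)
        theta, _, _ = estimate_null_overdispersion(x, s)
        # pure Poisson data carries no overdispersion signal: the moment
        # estimate is far above any biologically plausible value
        assert theta >= 1e3

    def test_gamma_poisson_recovers_theta(self):
        rng = np.random.default_rng(4)
        n, theta_true, mu = 5000, 10.0, 0.02
        s = rng.uniform(500, 2000, n)
        z = rng.gamma(theta_true, mu / theta_true, n)
        x = rng.poisson(s * z).astype(float)
        theta, _, _ = estimate_null_overdispersion(x, s)
        assert 7 <= theta <= 14

    def test_all_zero_gene_errors(self):
        with pytest.raises(NotModelableError):
            estimate_null_overdispersion(np.zeros(20), np.ones(20))


class TestWeightedElasticNet:
    @pytest.fixture
    def instance(self, rng):
        n, p = 40, 8
        G = rng.standard_normal((n, p))
        C = np.column_stack([np.ones(n), rng.standard_normal(n)])
        s = rng.uniform(0.5, 2, n)
        w = rng.uniform(0.5, 2, n)
        x = (G * s[:, None]) @ rng.standard_normal(p) + s + rng.standard_normal(n)
        return x, s, G, C, w

    def test_infinite_penalty_zeroes_beta(self, instance):
        x, s, G, C, w = instance
        beta, gamma = fit_weighted_elastic_net(x, s, G, C, w, lam=1e12)
        assert np.all(beta == 0)
        A = C * s[:, None]
        AtW = A.T * w
        ref = np.linalg.solve(AtW @ A, AtW @ x)
        assert np.allclose(gamma, ref, rtol=1e-8)

    def test_lambda_zero_matches_wls(self, instance):
        x, s, G, C, w = instance
        beta, gamma = fit_weighted_elastic_net(x, s, G, C, w, lam=0.0,
                                               standardize=False)
        A = np.column_stack([G * s[:, None], C * s[:, None]])
        AtW = A.T * w
        ref = np.linalg.solve(AtW @ A, AtW @ x)
        got = np.concatenate([beta, gamma])
        assert np.max(np.abs(got - ref)) <= 1e-6 * max(np.max(np.abs(ref)), 1)

    def test_nonfinite_inputs_error(self, instance):
        x, s, G, C, w = instance
        x = x.copy()
        x[0] = np.nan
        with pytest.raises(SctwasError, match="non-finite"):
            fit_weighted_elastic_net(x, s, G, C, w, lam=1.0)

    def test_refit_never_increases_objective_at_fixed_weights(self, instance):
        """One block update (refit at fixed w) cannot increase the loss."""
        x, s, G, C, w = instance
        lam = 2.0
        rng = np.random.default_rng(0)
        arbitrary_beta = rng.standard_normal(G.shape[1]) * 0.1
        arbitrary_gamma = rng.standard_normal(C.shape[1])
        before = weighted_enet_objective(x, s, G, C, w, lam,
                                         arbitrary_beta, arbitrary_gamma)
        beta, gamma = fit_weighted_elastic_net(x, s, G, C, w, lam,
                                               standardize=False)
        after = weighted_enet_objective(x, s, G, C, w, lam, beta, gamma)
        assert after <= before + 1e-9


class TestIRLS:
    def test_no_snps_reduces_to_covariate_fit(self, rng):
        n = 60
        s = rng.uniform(1e4, 1e5, n)
        x = rng.poisson(s * 1e-3).astype(float)
        res = irls_fit(x, s, np.zeros((n, 0)), None, lam=1.0, theta=None)
        assert res.beta.size == 0
        assert res.converged

    def test_deterministic_given_same_inputs(self, signal_cohort):
        co = signal_cohort
        x, s = co.pseudo_x.astype(float), co.pseudo_s.astype(float)
        theta, w0, _ = estimate_null_overdispersion(x, s)
        r1 = irls_fit(x, s, co.G, None, lam=1.0, theta=theta, weights0=w0)
        r2 = irls_fit(x, s, co.G, None, lam=1.0, theta=theta, weights0=w0)
        assert np.array_equal(r1.beta, r2.beta)
        assert r1.objective_trace == r2.objective_trace

    def test_poisson_limit_weights(self, signal_cohort):
        co = signal_cohort
        x, s = co.pseudo_x.astype(float), co.pseudo_s.astype(float)
        res = irls_fit(x, s, co.G, None, lam=1e3, theta=1e12)
        assert np.allclose(res.weights, 1 / (s * np.maximum(res.mu, 1e-10)),
                           rtol=1e-6)

    def test_support_recovery_single_strong_snp(self):
        """With one strong causal SNP the fit puts the largest weight on it."""
        hits = 0
        n_reps = 20
        for i in range(n_reps):
            rng = np.random.default_rng(500 + i)
            gb = simulate_genotypes(500, 15, rho=0.2, seed=rng)
            G = gb.standardized()
            mu = 1e-4 + G[:, 7] * 1e-5
            s = np.maximum(rng.lognormal(np.log(2.5e5), 0.3, 500), 1)
            z = rng.gamma(10.0, mu / 10.0)
            x = rng.poisson(s * z).astype(float)
            theta, w0, _ = estimate_null_overdispersion(x, s)
            lam = select_lambda_cv(x, s, G, seed=i)
            res = irls_fit(x, s, G, None, lam=lam, theta=theta, weights0=w0)
            if res.beta.any() and np.argmax(np.abs(res.beta)) == 7:
                hits += 1
        assert hits >= 0.9 * n_reps


class TestLambdaSelection:
    def test_single_grid_point_returned(self, signal_cohort):
        co = signal_cohort
        x, s = co.pseudo_x.astype(float), co.pseudo_s.astype(float)
        lam = select_lambda_cv(x, s, co.G, n_lambdas=1, seed=0)
        lam2, info = select_lambda_cv(x, s, co.G, n_lambdas=1, seed=0,
                                      return_info=True)
        assert lam == lam2 == info["grid"][0]

    def test_null_gene_selects_large_lambda(self):
        """Pure-noise genes push the CV choice to the top of the path."""
        near_max = 0
        n_reps = 20
        for i in range(n_reps):
            rng = np.random.default_rng(1000 + i)
            gb = simulate_genotypes(200, 20, rho=0.5, seed=rng)
            cfg = SimulationConfig(n_individuals=200, n_snps=20,
                                   cells_per_individual=84, null_stage1=True,
                                   n_replicates=1, seed=0)
            co = simulate_expression_counts(gb, cfg, seed=rng)
            lam, info = select_lambda_cv(co.pseudo_x.astype(float),
                                         co.pseudo_s.astype(float), co.G,
                                         seed=1000 + i, return_info=True)
            if lam >= 0.1 * info["grid"][0]:
                near_max += 1
        assert near_max >= 0.8 * n_reps

    def test_selected_loss_beats_endpoints(self, signal_cohort):
        co = signal_cohort
        x, s = co.pseudo_x.astype(float), co.pseudo_s.astype(float)
        _, info = select_lambda_cv(x, s, co.G, seed=3, return_info=True)
        best = info["cv_loss"].min()
        assert best <= info["cv_loss"][0] and best <= info["cv_loss"][-1]

    def test_too_few_samples_error(self, rng):
        with pytest.raises(SctwasError, match="samples"):
            select_lambda_cv(np.ones(8), np.ones(8), rng.standard_normal((8, 2)))


class TestPredictionEvaluation:
    def test_all_zero_beta_flagged(self, rng):
        n = 60
        s = rng.uniform(1e4, 1e5, n)
        x = rng.poisson(s * 1e-3).astype(float)
        G = np.zeros((n, 4))                     # no genetic signal possible
        p, info = evaluate_prediction_cv(x, s, G, seed=0, return_info=True)
        assert p == 1.0
        assert info["flag"] == "non-predictive"

    def test_strong_signal_detected(self, signal_cohort):
        co = signal_cohort
        p = evaluate_prediction_cv(co.pseudo_x.astype(float),
                                   co.pseudo_s.astype(float), co.G, seed=0)
        assert p < 0.05


class TestPredictGrex:
    def test_zero_beta_gives_zero(self):
        class M:
            beta = np.zeros(3)
        assert np.array_equal(predict_grex(np.ones((5, 3)), M()), np.zeros(5))

    def test_single_snp_doses(self):
        class M:
            beta = np.array([2.0])
        out = predict_grex(np.array([[0.0], [1.0], [2.0]]), M())
        assert np.array_equal(out, [0, 2, 4])

    def test_matches_explicit_loop(self, rng):
        class M:
            beta = rng.standard_normal(6)
        G = rng.standard_normal((10, 6))
        expected = np.array([sum(G[i, j] * M.beta[j] for j in range(6))
                             for i in range(10)])
        assert np.allclose(predict_grex(G, M()), expected)

    def test_dimension_mismatch_error(self):
        class M:
            beta = np.ones(3)
        with pytest.raises(SctwasError, match="harmonize"):
            predict_grex(np.ones((5, 4)), M())


class TestEstimatorAPI:
    def test_params_clone_and_fitted_attributes(self, signal_cohort):
        co = signal_cohort
        est = CountGReXRegressor(cv=5, random_state=7, n_lambdas=50)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(n_lambdas=40)
        assert est.get_params()["n_lambdas"] == 40
        est.fit(co.G, co.pseudo_x.astype(float),
                depth=co.pseudo_s.astype(float))
        for attr in ("beta_", "gamma_", "lambda_", "theta_", "weights_",
                     "n_iter_", "converged_"):
            assert hasattr(est, attr)
        assert est.theta_ > 0 and est.lambda_ >= 0
        assert np.all(est.weights_ > 0)
        pred = est.predict(co.G)
        assert pred.shape == (co.G.shape[0],)

    def test_depth_required(self, signal_cohort):
        with pytest.raises(ValueError, match="depth"):
            CountGReXRegressor().fit(signal_cohort.G,
                                     signal_cohort.pseudo_x.astype(float))
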