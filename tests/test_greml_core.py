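import numpy as np
import pytest

import oracles
from epigreml import (
    MethylationGREML,
    MixedModelSpec,
    SimulationTruth,
    ValidationError,
    blup_predict,
    build_design,
    compute_similarity,
    model_r2,
    reml_fit,
    reml_loglik,
    simulate_cohort,
    standardize,
    winsorize_matrix,
)


def _random_psd(rng, n):
    A = rng.standard_normal((n, n + 3))
    M = A @ A.T / (n + 3)
    return M / np.mean(np.diag(M))


def _small_spec(rng, n=6, q=2, with_batch=True):
    W = np.column_stack([np.ones(n), rng.standard_normal((n, q - 1))])
    y = rng.standard_normal(n) * 2.0
    batch = np.array(["a", "b"] * (n // 2)) if with_batch else None
    return MixedModelSpec(y=y, W=W, M=_random_psd(rng, n), batch=batch)


class TestRemlLoglik:
    def test_matches_naive_dense_algebra(self, rng):
        spec = _small_spec(rng)
        Z = oracles.batch_indicator(spec.batch)
        for params in [(0.5, 0.3, 1.0), (1.2, 0.01, 0.4), (0.0, 0.0, 2.0)]:
            got = reml_loglik(spec, params)
            want = oracles.naive_reml_loglik(spec.y, spec.W, params, spec.M, Z)
            assert got == pytest.approx(want, abs=1e-10)

    def test_reduces_to_ols_residual_likelihood_without_random_effects(self, rng):
        n, q = 20, 3
        W = np.column_stack([np.ones(n), rng.standard_normal((n, q - 1))])
        y = rng.standard_normal(n)
        spec = MixedModelSpec(y=y, W=W, M=_random_psd(rng, n))
        s2 = 0.7
        # closed form: V = s2*I gives -0.5[(n-q) log s2 + log|W'W| + RSS/s2]
        beta = np.linalg.lstsq(W, y, rcond=None)[0]
        rss = float(np.sum((y - W @ beta) ** 2))
        _, logdetWW = np.linalg.slogdet(W.T @ W)
        want = -0.5 * ((n - q) * np.log(s2) + logdetWW + rss / s2)
        assert reml_loglik(spec, (0.0, 0.0, s2)) == pytest.approx(want, abs=1e-8)

    def test_scaling_m_and_sigma2m_inversely_is_invariant(self, rng):
        spec = _small_spec(rng, n=8)
        c = 3.7
        spec_scaled = MixedModelSpec(
            y=spec.y, W=spec.W, M=spec.M * c, batch=spec.batch
        )
        a = reml_loglik(spec, (0.8, 0.2, 0.5))
        b = reml_loglik(spec_scaled, (0.8 / c, 0.2, 0.5))
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_residual_variance_rejected(self, rng):
        spec = _small_spec(rng)
        with pytest.raises(ValidationError):
            reml_loglik(spec, (0.5, 0.1, 0.0))


class TestRemlFit:
    def test_matches_exhaustive_grid_search_on_tiny_fixture(self):
        rng = np.random.default_rng(7)
        n = 10
        M = _random_psd(rng, n)
        W = np.ones((n, 1))
        L = np.linalg.cholesky(M + 1e-8 * np.eye(n))
        y = L @ rng.standard_normal(n) + 0.6 * rng.standard_normal(n)
        spec = MixedModelSpec(y=y, W=W, M=M)
        fit = reml_fit(spec)
        (gm, ge), grid_ll = oracles.grid_search_reml(y, W, M)
        assert fit.sigma2_m == pytest.approx(gm, abs=0.01)
        assert fit.sigma2_e == pytest.approx(ge, abs=0.01)
        assert fit.reml_loglik >= grid_ll - 1e-6

    def test_loglik_at_maximizer_not_below_start(self, rng):
        spec = _small_spec(rng, n=40)
        vary = float(np.var(spec.y, ddof=1))
        start = (vary / 3, vary / 3, vary / 3)
        fit = reml_fit(spec, start=start)
        assert fit.reml_loglik >= reml_loglik(spec, start) - 1e-8

    def test_null_data_gives_near_zero_methylation_share(self):
        shares = []
        for seed in range(20):
            cohort = simulate_cohort(
                200, 300, SimulationTruth(h2_m=0.0, var_batch=0.05,
                                          seed=500 + seed)
            )
            M = compute_similarity(standardize(winsorize_matrix(cohort.betas)))
            model = MethylationGREML.from_dataframe(
                cohort.pheno, "outcome", [], similarity=M
            )
            shares.append(model.fit().variance_share)
        assert np.mean(shares) < 0.05

    def test_recovers_moderate_h2_on_average(self):
        shares = []
        for seed in range(10):
            cohort = simulate_cohort(
                400, 1000, SimulationTruth(h2_m=0.5, var_batch=0.05,
                                           seed=900 + seed)
            )
            M = compute_similarity(standardize(winsorize_matrix(cohort.betas)))
            model = MethylationGREML.from_dataframe(
                cohort.pheno, "outcome", [], similarity=M
            )
            shares.append(model.fit().variance_share)
        assert 0.40 < np.mean(shares) < 0.60

    def test_shift_of_outcome_moves_only_the_intercept(self, rng):
        spec = _small_spec(rng, n=60)
        fit1 = reml_fit(spec)
        spec2 = MixedModelSpec(
            y=spec.y + 5.0, W=spec.W, M=spec.M, batch=spec.batch
        )
        fit2 = reml_fit(spec2)
        assert fit2.sigma2_m == pytest.approx(fit1.sigma2_m, abs=1e-6)
        assert fit2.sigma2_e == pytest.approx(fit1.sigma2_e, abs=1e-6)
        assert fit2.fe_params[0] == pytest.approx(fit1.fe_params[0] + 5.0, abs=1e-5)
        np.testing.assert_allclose(
            fit2.fe_params[1:], fit1.fe_params[1:], atol=1e-5
        )

    def test_matches_one_component_profile_closed_form(self, rng):
        # batch-free model: profile out sigma2_e along the ratio
        # delta = sigma2_m / sigma2_e in the eigenbasis of M
        from scipy.optimize import minimize_scalar

        n = 50
        M = _random_psd(rng, n)
        W = np.column_stack([np.ones(n), rng.standard_normal(n)])
        L = np.linalg.cholesky(M + 1e-10 * np.eye(n))
        y = 1.3 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
        spec = MixedModelSpec(y=y, W=W, M=M)
        fit = reml_fit(spec, tol=1e-12)

        D, U = np.linalg.eigh(M)
        yr, Wr = U.T @ y, U.T @ W
        q = W.shape[1]

        def profiled(log_delta):
            a = np.exp(log_delta) * np.clip(D, 0, None) + 1.0
            Ai = 1.0 / a
            B = Wr.T @ (Ai[:, None] * Wr)
            beta = np.linalg.solve(B, Wr.T @ (Ai * yr))
            r = yr - Wr @ beta
            s2e = float(r @ (Ai * r)) / (n - q)
            ll = -0.5 * (
                np.sum(np.log(a)) + (n - q) * np.log(s2e)
                + np.linalg.slogdet(B)[1] + (n - q)
            )
            return -ll, s2e

        res = minimize_scalar(
            lambda x: profiled(x)[0], bounds=(-12, 12), method="bounded",
            options={"xatol": 1e-12},
        )
        delta = np.exp(res.x)
        s2e = profiled(res.x)[1]
        assert fit.sigma2_e == pytest.approx(s2e, abs=1e-6)
        assert fit.sigma2_m == pytest.approx(delta * s2e, abs=1e-6)


class TestBlup:
    def test_fixed_effects_only_when_components_vanish(self, rng):
        n = 30
        W = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = W @ np.array([1.0, 0.5]) + 0.1 * rng.standard_normal(n)
        spec = MixedModelSpec(y=y, W=W)  # residual-only model
        fit = reml_fit(spec)
        W_test = np.column_stack([np.ones(4), rng.standard_normal(4)])
        pred = blup_predict(fit, spec, M_cross=None, W_test=W_test)
        np.testing.assert_allclose(pred, W_test @ fit.fe_params, atol=1e-12)

    def test_uninformative_test_sample_gets_covariate_prediction(self, rng):
        spec = _small_spec(rng, n=40)
        fit = reml_fit(spec)
        W_test = np.array([[1.0, 0.3]])
        pred = blup_predict(
            fit, spec, M_cross=np.zeros((1, 40)), W_test=W_test,
            batch_test=np.array(["unseen-batch"]),
        )
        assert pred[0] == pytest.approx(
            float((W_test @ fit.fe_params)[0]), abs=1e-12
        )

    def test_matches_henderson_mixed_model_equations(self, rng):
        n_train, n_test = 12, 5
        n = n_train + n_test
        M_full = _random_psd(rng, n)
        M_full += 0.05 * np.eye(n)  # keep the train block well-conditioned
        M_full /= np.mean(np.diag(M_full))
        W = np.column_stack([np.ones(n), rng.standard_normal(n)])
        batch = np.array(["a", "b", "c"] * (n // 3) + ["a"] * (n % 3))
        y = rng.standard_normal(n)
        train = np.arange(n_train)
        test = np.arange(n_train, n)
        spec = MixedModelSpec(
            y=y[train], W=W[train], M=M_full[np.ix_(train, train)],
            batch=batch[train],
        )
        params = (0.8, 0.3, 0.5)
        fit = reml_fit(spec, start=params, max_iter=0)  # evaluate at fixed params
        fit.sigma2_m, fit.sigma2_batch, fit.sigma2_e = params
        pred = blup_predict(
            fit, spec, M_cross=M_full[np.ix_(test, train)],
            W_test=W[test], batch_test=batch[test],
        )

        Z = oracles.batch_indicator(batch[train])
        beta_h, g_train, u = oracles.henderson_blup(
            y[train], W[train], M_full[np.ix_(train, train)], Z, *params
        )
        g_test = M_full[np.ix_(test, train)] @ np.linalg.solve(
            M_full[np.ix_(train, train)], g_train
        )
        levels = list(dict.fromkeys(batch[train].tolist()))
        u_test = np.array([u[levels.index(b)] for b in batch[test]])
        expected = W[test] @ beta_h + g_test + u_test
        np.testing.assert_allclose(pred, expected, atol=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        spec = _small_spec(rng, n=10)
        fit = reml_fit(spec)
        with pytest.raises(ValidationError):
            blup_predict(fit, spec, M_cross=np.zeros((2, 9)),
                         W_test=np.ones((2, 2)))


class TestModelR2:
    def test_perfect_and_sign_flipped_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert model_r2(y, y) == pytest.approx(1.0)
        assert model_r2(-y, y) == pytest.approx(1.0)

    def test_hand_computed_squared_pearson(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        obs = np.array([1.0, 2.0, 3.0, 5.0])
        num = np.sum((pred - pred.mean()) * (obs - obs.mean()))
        want = num**2 / (
            np.sum((pred - pred.mean()) ** 2) * np.sum((obs - obs.mean()) ** 2)
        )
        assert model_r2(pred, obs) == pytest.approx(want, abs=1e-12)

    def test_constant_predictions_warn_and_return_zero(self):
        with pytest.warns(RuntimeWarning):
            assert model_r2(np.ones(5), np.arange(5.0)) == 0.0

    def test_short_vectors_rejected(self):
        with pytest.raises(ValidationError):
            model_r2(np.ones(2), np.ones(2))


class TestDesign:
    def test_dummy_encoding_drops_reference_level(self, small_cohort):
        W, names = build_design(
            small_cohort.pheno, ["sex", "maternal_age", "education"]
        )
        assert names[0] == "intercept"
        assert sum(n.startswith("education_") for n in names) == 2
        assert W.shape[1] == len(names)
        assert np.linalg.matrix_rank(W) == W.shape[1]

    def test_rank_deficient_design_rejected(self, rng):
        n = 20
        x = rng.standard_normal(n)
        W = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValidationError, match="rank"):
            MixedModelSpec(y=rng.standard_normal(n), W=W)

    def test_missing_covariate_cells_rejected(self, small_cohort):
        pheno = small_cohort.pheno.copy()
        pheno.loc[0, "maternal_age"] = np.nan
        with pytest.raises(ValidationError, match="imputation"):
            build_design(pheno, ["maternal_age"])
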