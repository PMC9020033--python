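import numpy as np
import pytest

from epigreml import (
    SimulationTruth,
    ValidationError,
    compute_similarity,
    inverse_variance_pool,
    run_cv,
    simulate_cohort,
    simulate_two_cohorts,
    standardize,
    winsorize_matrix,
    write_cohort,
)


class TestSimulateCohort:
    def test_same_config_and_seed_reproduces_files(self, tmp_path):
        truth = SimulationTruth(h2_m=0.4, var_batch=0.05, seed=13)
        paths_a = write_cohort(
            simulate_cohort(40, 60, truth, missing_rate=0.1), tmp_path / "a"
        )
        paths_b = write_cohort(
            simulate_cohort(40, 60, truth, missing_rate=0.1), tmp_path / "b"
        )
        for key in paths_a:
            assert paths_a[key].read_text() == paths_b[key].read_text()

    def test_betas_strictly_inside_unit_interval_and_complete(self):
        cohort = simulate_cohort(50, 80, SimulationTruth(h2_m=0.3, seed=2))
        assert cohort.betas.values.min() > 0.0
        assert cohort.betas.values.max() < 1.0
        assert not np.isnan(cohort.betas.values).any()

    def test_null_truth_decouples_outcome_from_causal_score(self):
        r2 = []
        for seed in range(10):
            cohort = simulate_cohort(
                1000, 100, SimulationTruth(h2_m=0.0, seed=300 + seed)
            )
            X = cohort.betas.values
            X_std = (X - X.mean(axis=0)) / X.std(axis=0)
            idx = [cohort.betas.probe_ids.index(p)
                   for p in cohort.truth.causal_probes]
            score = X_std[:, idx] @ np.array(
                list(cohort.truth.causal_probes.values())
            )
            r = np.corrcoef(score, cohort.pheno["outcome"])[0, 1]
            r2.append(r**2)
        assert np.mean(r2) < 0.01

    def test_variance_decomposition_matches_truth_on_average(self):
        shares = []
        for seed in range(20):
            cohort = simulate_cohort(
                2000, 150,
                SimulationTruth(h2_m=0.4, var_batch=0.1, var_covariates=0.1,
                                seed=400 + seed),
            )
            shares.append(cohort.variance_decomposition()["methylation"])
        assert 0.35 < np.mean(shares) < 0.45

    def test_large_sample_decomposition_close_to_truth(self):
        truth = SimulationTruth(
            h2_m=0.3, var_batch=0.1, var_covariates=0.2, seed=9
        )
        decomp = simulate_cohort(5000, 100, truth).variance_decomposition()
        assert decomp["methylation"] == pytest.approx(truth.h2_m, abs=0.05)
        assert decomp["batch"] == pytest.approx(truth.var_batch, abs=0.05)
        assert decomp["covariates"] == pytest.approx(truth.var_covariates, abs=0.05)
        assert decomp["residual"] == pytest.approx(truth.var_resid, abs=0.05)

    def test_within_block_beta_correlation_tracks_configured_correlation(self):
        from scipy.stats import spearmanr

        mean_corr = []
        rhos = [0.1, 0.3, 0.5, 0.7, 0.9]
        for rho in rhos:
            cohort = simulate_cohort(
                400, 40, SimulationTruth(h2_m=0.2, seed=50),
                block_structure=(5, rho), n_chromosomes=1,
            )
            X = cohort.betas.values
            rs = [
                np.corrcoef(X[:, j], X[:, j + 1])[0, 1]
                for start in range(0, 40, 5)
                for j in range(start, start + 4)
            ]
            mean_corr.append(np.mean(rs))
        assert spearmanr(rhos, mean_corr).statistic > 0.9

    def test_missingness_mechanisms(self):
        truth = SimulationTruth(h2_m=0.3, seed=6)
        mcar = simulate_cohort(500, 20, truth, missing_rate=0.2)
        frac = mcar.pheno["outcome"].isna().mean()
        assert 0.1 < frac < 0.3
        assert mcar.pheno["batch"].notna().all()
        mar = simulate_cohort(
            500, 20, truth, missing_rate=0.2, missing_mechanism="mar"
        )
        assert mar.pheno["maternal_age"].notna().all()
        assert 0.1 < mar.pheno["outcome"].isna().mean() < 0.3
        # MAR: missingness depends on the always-observed covariate
        miss = mar.pheno["outcome"].isna()
        assert (
            mar.pheno.loc[miss, "maternal_age"].mean()
            > mar.pheno.loc[~miss, "maternal_age"].mean()
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 1, "p": 10},
            {"n": 10, "p": 5, "block_structure": (8, 0.5)},
            {"n": 10, "p": 5, "missing_rate": 1.0},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        n = kwargs.pop("n")
        p = kwargs.pop("p")
        with pytest.raises(ValidationError):
            simulate_cohort(n, p, SimulationTruth(h2_m=0.3, seed=0), **kwargs)

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValidationError):
            SimulationTruth(h2_m=1.2)


class TestTwoCohorts:
    def test_disjoint_sample_ids_and_distinct_draws(self):
        truth = SimulationTruth(h2_m=0.3, var_batch=0.05, seed=19)
        a, b = simulate_two_cohorts(truth, (300, 600), p=50)
        assert a.betas.n_samples == 300 and b.betas.n_samples == 600
        assert not set(a.betas.sample_ids) & set(b.betas.sample_ids)
        assert not np.array_equal(a.betas.values[:300], b.betas.values[:300])
        assert a.truth.h2_m == b.truth.h2_m

    def test_pooled_delta_lies_between_cohort_estimates(self):
        truth = SimulationTruth(h2_m=0.5, var_batch=0.05, seed=23)
        a, b = simulate_two_cohorts(truth, (120, 150), p=200)
        estimates = []
        for cohort in (a, b):
            M = compute_similarity(standardize(winsorize_matrix(cohort.betas)))
            res = run_cv("outcome", cohort.pheno, M, ["sex"], n_splits=6, seed=3)
            estimates.append((res.mean_delta, res.sd_cv))
        pooled = inverse_variance_pool(estimates)
        lo, hi = sorted(e for e, _ in estimates)
        assert lo <= pooled.estimate <= hi
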