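"""Compositional regression: design, OLS, pivot refits, model suite."""

import numpy as np
import pandas as pd
import pytest

import timecoda as tc
from timecoda import coda
from timecoda import regression as reg
from conftest import ols_normal_equations


def _design_fixture(n=60, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    comps = coda.ilr_inverse(rng.normal([-1.7, -0.1], 0.5, size=(n, 2)))
    covariates = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "male": rng.integers(0, 2, n),
            "age": rng.normal(73, 5, n),
            "icv": rng.normal(1.43e6, 1.5e5, n),
            "education": rng.integers(0, 2, n),
            "bmi_under": rng.integers(0, 2, n),
            "bmi_over": rng.integers(0, 2, n),
            "smoker": rng.integers(0, 2, n),
            "alcohol": rng.integers(0, 2, n),
            "med_hypertension": rng.integers(0, 2, n),
            "med_dyslipidemia": rng.integers(0, 2, n),
            "med_diabetes": rng.integers(0, 2, n),
        }
    )
    z = coda.ilr_pivot(comps)
    y = 3000 + 50 * z[:, 0] - 10 * z[:, 1] + 0.002 * covariates["icv"] \
        - 30 * covariates["age"] + noise * rng.standard_normal(n)
    return comps, covariates, pd.Series(y, name="right_hv")


class TestBuildDesign:
    def test_model_column_counts(self):
        comps, covariates, y = _design_fixture()
        for level, extra in [(1, 0), (2, 3), (3, 4), (4, 8), (5, 11)]:
            X, _ = reg.build_design(comps, covariates, reg.ModelSpec("right_hv", level))
            assert X.shape[1] == 3 + extra
        X, _ = reg.build_design(
            comps, covariates, reg.ModelSpec("right_hv", 5, ratio=True)
        )
        assert X.shape[1] == 3 + 10 and "icv" not in X.columns

    def test_listwise_deletion_of_incomplete_rows(self):
        comps, covariates, y = _design_fixture(n=30)
        covariates.loc[3, "age"] = np.nan
        X, yy = reg.build_design(
            comps, covariates, reg.ModelSpec("right_hv", 5), outcome=y
        )
        assert len(X) == 29 and len(yy) == 29


class TestFitOls:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, p = int(rng.integers(15, 60)), int(rng.integers(2, 6))
            X = pd.DataFrame(rng.standard_normal((n, p)),
                             columns=[f"x{j}" for j in range(p)])
            X["x0"] = 1.0
            y = rng.standard_normal(n)
            fit = reg.fit_ols(X, y)
            beta, se, pvals, (lo, hi), sigma2 = ols_normal_equations(X, y)
            np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
            np.testing.assert_allclose(fit.bse.to_numpy(), se, atol=1e-8)
            np.testing.assert_allclose(fit.pvalues.to_numpy(), pvals, atol=1e-8)
            np.testing.assert_allclose(fit.conf_int["low"].to_numpy(), lo, atol=1e-8)
            np.testing.assert_allclose(fit.conf_int["high"].to_numpy(), hi, atol=1e-8)
            assert fit.sigma2 == pytest.approx(sigma2, abs=1e-10)

    def test_noiseless_outcome_interpolated_exactly(self):
        comps, covariates, y = _design_fixture(noise=0.0)
        X, yy = reg.build_design(comps, covariates, reg.ModelSpec("right_hv", 2),
                                 outcome=y)
        fit = reg.fit_ols(X, yy)
        np.testing.assert_allclose(fit.resid, 0.0, atol=1e-6)
        assert fit.params["z1"] == pytest.approx(50.0, abs=1e-8)
        assert fit.params["z2"] == pytest.approx(-10.0, abs=1e-8)

    def test_duplicate_column_is_rank_error(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"const": 1.0, "a": rng.standard_normal(20)})
        X["b"] = X["a"]
        with pytest.raises(ValueError, match="rank deficient"):
            reg.fit_ols(X, rng.standard_normal(20))

    def test_constant_sex_column_flagged(self):
        comps, covariates, y = _design_fixture(n=40)
        covariates["male"] = 1  # all-male cohort: collinear with intercept
        X, yy = reg.build_design(comps, covariates, reg.ModelSpec("right_hv", 2),
                                 outcome=y)
        with pytest.raises(ValueError, match="male"):
            reg.fit_ols(X, yy)


class TestPivotModels:
    def test_z1_coefficients_sum_to_zero(self, default_cohort):
        cfg, table, truth = default_cohort
        for level in (1, 3, 5):
            fits, _ = reg.fit_pivot_models(
                truth.compositions(), table, table["right_hv"],
                reg.ModelSpec("right_hv", level),
            )
            assert abs(sum(f.beta_z1 for f in fits.values())) < 1e-8

    def test_fitted_values_identical_across_pivots(self, default_cohort):
        # fit_pivot_models raises internally if pivots disagree; also verify
        # the log-contrast reproduces each pivot's z1 slope
        cfg, table, truth = default_cohort
        fits, lc = reg.fit_pivot_models(
            truth.compositions(), table, table["right_hv"],
            reg.ModelSpec("right_hv", 5),
        )
        a = lc.as_array()
        for i, part in enumerate(coda.PARTS):
            assert fits[part].beta_z1 == pytest.approx(
                np.sqrt(3 / 2) * a[i], abs=1e-8
            )

    def test_noiseless_generator_betas_recovered_exactly(self):
        cfg = tc.CohortConfig(n_participants=100, seed=77, noise_sd=0.0,
                              left_noise_sd=0.0)
        cov, truth = tc.generate_cohort(cfg)
        out = tc.generate_outcomes(cov, truth, cfg)
        table = cov.merge(out, on="participant_id")
        fits, _ = reg.fit_pivot_models(
            truth.compositions(), table, table["right_hv"],
            reg.ModelSpec("right_hv", 5),
        )
        assert fits["mvpa"].beta_z1 == pytest.approx(cfg.beta_z1, abs=1e-6)

    def test_relabeling_behaviors_permutes_reported_betas(self):
        comps, covariates, y = _design_fixture(noise=30.0)
        fits, _ = reg.fit_pivot_models(comps, covariates, y,
                                       reg.ModelSpec("right_hv", 2))
        swapped = comps[:, [1, 0, 2]]  # call SB what was LPA and vice versa
        fits_s, _ = reg.fit_pivot_models(swapped, covariates, y,
                                         reg.ModelSpec("right_hv", 2))
        assert fits_s["sb"].beta_z1 == pytest.approx(fits["lpa"].beta_z1, abs=1e-8)
        assert fits_s["lpa"].beta_z1 == pytest.approx(fits["sb"].beta_z1, abs=1e-8)
        assert fits_s["mvpa"].beta_z1 == pytest.approx(fits["mvpa"].beta_z1, abs=1e-8)

    def test_parameter_recovery_sanity(self):
        # small replicate check; the full 200-replicate study lives in the
        # acceptance suite
        est = []
        for seed in range(20):
            cfg = tc.CohortConfig(n_participants=485, seed=1000 + seed)
            cov, truth = tc.generate_cohort(cfg)
            out = tc.generate_outcomes(cov, truth, cfg)
            table = cov.merge(out, on="participant_id")
            X, y = reg.build_design(truth.compositions(), table,
                                    reg.ModelSpec("right_hv", 5), outcome=table["right_hv"])
            est.append(reg.fit_ols(X, y).params["z1"])
        assert np.mean(est) == pytest.approx(57.1, rel=0.15)


class TestModelSuite:
    def test_row_counts(self, default_cohort):
        cfg, table, truth = default_cohort
        suite = reg.run_model_suite(truth.compositions(), table, table)
        volume = suite[~suite["outcome"].str.endswith("_ratio")]
        ratio = suite[suite["outcome"].str.endswith("_ratio")]
        assert len(volume) == 30  # 5 models x 2 sides x 3 pivots
        assert len(ratio) == 30  # 15 ratio rows per side
        assert set(suite["pivot"]) == set(coda.PARTS)

    def test_ratio_betas_proportional_when_icv_constant(self):
        comps, covariates, y = _design_fixture(n=50, noise=20.0)
        covariates["icv"] = 1.5e6
        outcomes = pd.DataFrame({"right_hv": y, "left_hv": y})
        suite = reg.run_model_suite(comps, covariates, outcomes,
                                    outcome_columns=("right_hv",), levels=(1,))
        vol = suite[suite["outcome"] == "right_hv"].set_index("pivot")["beta"]
        rat = suite[suite["outcome"] == "right_hv_ratio"].set_index("pivot")["beta"]
        np.testing.assert_allclose(rat, vol / 1.5e6 * reg.RATIO_SCALE, rtol=1e-8)

    def test_confounding_shifts_unadjusted_estimate(self):
        # age raises z1 while independently lowering the outcome: the
        # unadjusted MVPA beta must be biased downward relative to model 2+
        cfg = tc.CohortConfig(n_participants=400, seed=55, age_ilr_slope=0.06,
                              noise_sd=50.0)
        cov, truth = tc.generate_cohort(cfg)
        out = tc.generate_outcomes(cov, truth, cfg)
        table = cov.merge(out, on="participant_id")
        suite = reg.run_model_suite(truth.compositions(), table, table,
                                    outcome_columns=("right_hv",), levels=(1, 5),
                                    include_ratio=False)
        mvpa = suite[suite["pivot"] == "mvpa"].set_index("model")["beta"]
        assert mvpa[1] < mvpa[5]

    def test_formatted_table_shape(self, default_cohort):
        cfg, table, truth = default_cohort
        suite = reg.run_model_suite(truth.compositions(), table, table,
                                    levels=(5,), include_ratio=False)
        formatted = reg.format_coefficient_table(suite)
        assert list(formatted.columns) == [
            "outcome", "model", "sb_beta", "sb_p", "lpa_beta", "lpa_p",
            "mvpa_beta", "mvpa_p",
        ]
        assert "(" in formatted.loc[0, "mvpa_beta"]
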