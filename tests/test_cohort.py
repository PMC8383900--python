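"""Cohort generator calibration and the association-analysis machinery."""

import numpy as np
import pandas as pd
import pytest

import fundtess as ft
from fundtess.cohort import PREDICTORS, _numeric_column
from fundtess.errors import CohortTooSmall, ConstantPredictor, EmptyModel


def brute_vif_from_corr(sigma: np.ndarray, j: int) -> float:
    """VIF_j = 1/(1 - R_j^2) via explicit regression on the correlation scale."""
    others = [k for k in range(sigma.shape[0]) if k != j]
    s_oo = sigma[np.ix_(others, others)]
    s_oj = sigma[others, j]
    r2 = s_oj @ np.linalg.solve(s_oo, s_oj)
    return 1.0 / (1.0 - r2)


class TestCalibration:
    def test_solved_matrix_is_a_correlation_matrix(self, calibration):
        sigma = ft.calibrate_predictor_corr(calibration)
        assert np.allclose(np.diag(sigma), 1.0)
        assert np.allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma).min() >= -1e-8

    def test_model_r_squared_reproduced(self, calibration):
        sigma = ft.calibrate_predictor_corr(calibration)
        beta = calibration.beta_vector
        assert abs(beta @ sigma @ beta - calibration.target_model_R**2) <= 1e-3

    def test_vifs_match_brute_force_regressions(self, calibration):
        sigma = ft.calibrate_predictor_corr(calibration)
        targets = dict(calibration.target_vifs)
        for j, name in enumerate(PREDICTORS):
            assert abs(brute_vif_from_corr(sigma, j) - targets[name]) <= 0.05

    def test_implied_age_correlation(self, calibration):
        sigma = ft.calibrate_predictor_corr(calibration)
        age_r = (sigma @ calibration.beta_vector)[0]
        assert abs(age_r - calibration.target_age_r) <= 0.02


class TestGeneration:
    def test_ftd_clipped_to_unit_interval(self, cohort_3074):
        assert cohort_3074["ftd"].between(0.0, 1.0).all()

    def test_mean_age_matches_population(self, cohort_3074):
        assert abs(cohort_3074["age"].mean() - 64.1) <= 0.5

    def test_age_within_declared_range(self, cohort_3074):
        assert cohort_3074["age"].between(50, 93).all()

    def test_spherical_equivalent_identity_is_exact(self, cohort_3074):
        se = cohort_3074["sphere"] + cohort_3074["cylinder"] / 2.0
        assert (se == cohort_3074["se"]).all()

    def test_myopic_stratum_mean_refraction(self, cohort_3074):
        myo = cohort_3074[ft.classify_refraction(cohort_3074["se"]) == "myopia"]
        assert abs(myo["se"].mean() - (-2.16)) <= 0.15

    def test_small_cohort_rejected(self, calibration):
        with pytest.raises(CohortTooSmall):
            ft.generate_cohort(10, calibration, seed=0)

    def test_same_seed_reproduces_cohort(self, calibration):
        a = ft.generate_cohort(100, calibration, seed=3)
        b = ft.generate_cohort(100, calibration, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_observed_correlations_converge_to_calibrated(self, calibration,
                                                          cohort_3074):
        sigma = ft.calibrate_predictor_corr(calibration)
        x = np.column_stack([_numeric_column(cohort_3074, p)
                             for p in PREDICTORS])
        emp = np.corrcoef(x, rowvar=False)
        assert np.abs(emp - sigma).max() < 0.06

    def test_csv_round_trip(self, tmp_path, calibration):
        cohort = ft.generate_cohort(200, calibration, seed=5)
        ft.write_cohort(cohort, tmp_path / "c.csv")
        again = ft.read_cohort(tmp_path / "c.csv")
        assert list(again.columns) == list(ft.cohort.COHORT_COLUMNS)
        assert np.allclose(again["ftd"], cohort["ftd"])


class TestUnivariate:
    def test_standardized_beta_equals_pearson_r(self, cohort_3074):
        rows = ft.univariate_screen(cohort_3074, predictors=["age", "sfct"])
        for name in ("age", "sfct"):
            r = np.corrcoef(cohort_3074[name], cohort_3074["ftd"])[0, 1]
            assert rows.loc[name, "beta"] == pytest.approx(r, abs=1e-10)

    def test_coefficients_match_normal_equations(self, rng):
        x = rng.standard_normal(20)
        y = 0.3 * x + rng.standard_normal(20) * 0.1
        cohort = pd.DataFrame({"x": x, "ftd": y})
        row = ft.univariate_screen(cohort, predictors=["x"]).loc["x"]
        design = np.column_stack([np.ones(20), x])
        coef = np.linalg.solve(design.T @ design, design.T @ y)
        assert row["B"] == pytest.approx(coef[1], abs=1e-10)
        assert row["ci_low"] < coef[1] < row["ci_high"]

    def test_constant_predictor_raises(self, rng):
        cohort = pd.DataFrame({"flat": np.ones(30),
                               "ftd": rng.uniform(size=30)})
        with pytest.raises(ConstantPredictor):
            ft.univariate_screen(cohort, predictors=["flat"])


class TestStepwise:
    def test_duplicated_predictor_is_vif_pruned(self, cohort_3074, rng):
        cohort = cohort_3074.copy()
        cohort["age_copy"] = (cohort["age"]
                              + rng.normal(0, cohort["age"].std() * 0.02,
                                           len(cohort)))
        report = ft.multivariate_stepwise(
            cohort, list(PREDICTORS) + ["age_copy"])
        kept = set(report.terms.index)
        assert not {"age", "age_copy"} <= kept
        assert any("VIF" in s for s in report.steps)

    def test_pure_noise_predictor_usually_eliminated(self, calibration):
        removed = 0
        for seed in range(20):
            cohort = ft.generate_cohort(1500, calibration, seed=1000 + seed)
            cohort["noise"] = np.random.default_rng(seed).standard_normal(
                len(cohort))
            report = ft.multivariate_stepwise(cohort,
                                              list(PREDICTORS) + ["noise"])
            removed += "noise" not in report.terms.index
        assert removed >= 18

    def test_six_predictor_model_recovers_table_coefficients(self, cohort_3074,
                                                             calibration):
        report = ft.multivariate_stepwise(cohort_3074, list(PREDICTORS))
        betas = dict(calibration.std_betas)
        assert set(report.terms.index) == set(PREDICTORS)
        for name in PREDICTORS:
            width = (report.terms.loc[name, "ci_high"]
                     - report.terms.loc[name, "ci_low"])
            b_std = report.terms.loc[name, "beta"]
            assert abs(b_std - betas[name]) <= 0.05, name
            assert width > 0

    def test_empty_candidates_raise(self, cohort_3074):
        with pytest.raises(EmptyModel):
            ft.multivariate_stepwise(cohort_3074, [])


class TestVIF:
    def test_vif_matches_independent_regression(self, cohort_3074):
        vifs = ft.vif(cohort_3074, list(PREDICTORS))
        x = np.column_stack([_numeric_column(cohort_3074, p)
                             for p in PREDICTORS])
        for j, name in enumerate(PREDICTORS):
            others = np.delete(x, j, axis=1)
            design = np.column_stack([np.ones(len(x)), others])
            coef, *_ = np.linalg.lstsq(design, x[:, j], rcond=None)
            resid = x[:, j] - design @ coef
            r2 = 1.0 - resid.var() / x[:, j].var()
            assert vifs[name] == pytest.approx(1.0 / (1.0 - r2), abs=1e-10)


class TestStrata:
    def test_partitions_cover_cohort(self, cohort_3074):
        strata = ft.stratified_summaries(cohort_3074)
        assert strata["age_groups"]["n"].sum() == len(cohort_3074)
        assert strata["sex"]["n"].sum() == len(cohort_3074)
        assert strata["refraction"]["n"].sum() == len(cohort_3074)

    def test_boundary_refraction_is_emmetropic(self):
        classes = ft.classify_refraction(np.array([-0.25, 0.25, -0.26, 0.26]))
        assert list(classes) == ["emmetropia", "emmetropia",
                                 "myopia", "hypermetropia"]

    def test_age_effect_detected_by_anova(self, cohort_3074):
        strata = ft.stratified_summaries(cohort_3074)
        assert strata["age_anova"]["p"] < 0.001
        assert strata["sex_ttest"]["p"] < 0.001

    def test_empty_stratum_reported_not_raised(self, calibration):
        cohort = ft.generate_cohort(100, calibration, seed=2).copy()
        cohort["se"] = 5.0  # everyone hypermetropic
        strata = ft.stratified_summaries(cohort)
        myo = strata["refraction"].loc["myopia"]
        assert myo["n"] == 0 and np.isnan(myo["ftd_mean"])
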