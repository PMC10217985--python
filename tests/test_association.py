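"""Tests for the logistic association grid against closed-form oracles."""

import math

import numpy as np
import pytest

from sscpgx.association import (
    NoVariationError,
    Z975,
    fit_logistic,
    forest_plot_data,
    odds_ratio_for_cell,
    results_to_frame,
    run_association_grid,
    stratum_members,
)
from sscpgx.cohort_model import OUTCOME_NAMES, STRATA, ValidationError
from sscpgx.synthetic_data import generate_cohort, study_like_config


def table_to_xy(a, b, c, d):
    """2×2 table (exposed events a, exposed non-events b, unexposed
    events c, unexposed non-events d) as response/exposure vectors."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, np.column_stack([np.ones_like(x), x])


class TestFitLogistic:
    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(0)
        x = np.tile([0.0, 1.0], 500)
        y = rng.random(1000) < 0.3
        fit = fit_logistic(y.astype(float), np.column_stack([np.ones(1000), x]))
        assert fit.converged and not fit.separated
        z = fit.coefficients[1] / fit.standard_errors[1]
        assert abs(z) < 3.0

    def test_saturated_2x2_equals_cross_product_ratio(self):
        y, X = table_to_xy(10, 5, 4, 20)
        fit = fit_logistic(y, X)
        assert math.exp(fit.coefficients[1]) == pytest.approx(10.0, rel=1e-6)
        woolf_se = math.sqrt(1 / 10 + 1 / 5 + 1 / 4 + 1 / 20)
        assert fit.standard_errors[1] == pytest.approx(woolf_se, rel=1e-6)

    def test_perfect_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        fit = fit_logistic(y, np.column_stack([np.ones(20), x]))
        assert fit.separated

    def test_no_variation_raises(self):
        with pytest.raises(NoVariationError):
            fit_logistic(np.ones(10), np.ones((10, 1)))

    def test_firth_finite_under_separation(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        fit = fit_logistic(x, np.column_stack([np.ones(20), x]), firth=True)
        assert fit.method == "firth"
        assert np.isfinite(fit.coefficients).all()
        assert np.isfinite(fit.standard_errors).all()

    def test_firth_matches_mle_when_well_behaved(self):
        y, X = table_to_xy(30, 20, 15, 35)
        mle = fit_logistic(y, X)
        firth = fit_logistic(y, X, firth=True)
        # Firth shrinks toward zero but only slightly at these cell sizes
        assert firth.coefficients[1] == pytest.approx(mle.coefficients[1], abs=0.1)


def _cell_cohort(seed=3, n=400, **overrides):
    cfg = study_like_config(seed=seed, n_subjects=n, **overrides)
    cohort, _ = generate_cohort(cfg)
    return cohort


class TestOddsRatioCell:
    def test_wald_ci_symmetric_on_log_scale(self):
        cohort = _cell_cohort()
        r = odds_ratio_for_cell(cohort, "rs1801133", "pf", "all", adjust=False)
        assert r.estimable
        assert math.log(r.ci_high) - math.log(r.odds_ratio) == pytest.approx(
            math.log(r.odds_ratio) - math.log(r.ci_low), abs=1e-9
        )
        assert r.ci_low <= r.odds_ratio <= r.ci_high

    def test_exposure_recode_inverts_odds_ratio(self):
        y, X = table_to_xy(10, 5, 4, 20)
        fit = fit_logistic(y, X)
        Xr = X.copy()
        Xr[:, 1] = 1 - Xr[:, 1]
        fit_r = fit_logistic(y, Xr)
        assert math.exp(fit_r.coefficients[1]) == pytest.approx(
            1 / math.exp(fit.coefficients[1]), rel=1e-9
        )

    def test_adjusted_equals_unadjusted_under_independence(self):
        # age and sex simulated independent of genotype and outcome
        cfg = study_like_config(seed=11, n_subjects=3000)
        models = {
            name: type(m)(
                intercept=-1.2, log_or_per_marker=m.log_or_per_marker,
                log_or_age_per_year=0.0, log_or_male=0.0,
            )
            for name, m in cfg.outcome_models.items()
        }
        cohort, _ = generate_cohort(
            study_like_config(seed=11, n_subjects=3000, outcome_models=models)
        )
        una = odds_ratio_for_cell(cohort, "rs1801133", "rvsp_high", "all", False)
        adj = odds_ratio_for_cell(cohort, "rs1801133", "rvsp_high", "all", True)
        # with covariates independent of everything the exposure OR is
        # essentially unchanged by adjustment (non-collapsibility is
        # negligible at these effect sizes)
        assert adj.odds_ratio == pytest.approx(una.odds_ratio, rel=0.05)

    def test_zero_event_stratum_flagged(self):
        cfg = study_like_config(seed=5)
        models = dict(cfg.outcome_models)
        models["huv"] = type(models["huv"])(intercept=-30.0)
        cohort, _ = generate_cohort(study_like_config(seed=5, outcome_models=models))
        r = odds_ratio_for_cell(cohort, "rs1801133", "huv", "AZA", adjust=True)
        assert not r.estimable and r.note == "no events"
        assert math.isnan(r.odds_ratio) and math.isnan(r.p_value)

    def test_unknown_stratum_is_config_error(self):
        with pytest.raises(ValidationError):
            odds_ratio_for_cell(_cell_cohort(), "rs1801133", "pf", "GC", False)


class TestStratumPolicy:
    def test_both_policy_counts_combination_subjects_twice(self, study_cohort):
        cohort, _ = study_cohort
        n_combo = sum(1 for s in cohort.subjects if s.therapy == "AZA+MTX")
        aza_both = len(stratum_members(cohort, "AZA", "both"))
        aza_excl = len(stratum_members(cohort, "AZA", "exclusive"))
        assert aza_both - aza_excl == n_combo
        assert all(
            s.therapy != "AZA+MTX" for s in stratum_members(cohort, "Other", "both")
        )


class TestGrid:
    def test_cardinality_and_order(self, study_cohort):
        cohort, _ = study_cohort
        results = run_association_grid(cohort)
        # 4 markers (pre-collapse) × 5 outcomes × 4 strata × 2 adjustments
        assert len(results) == 4 * 5 * 4 * 2
        keys = [(r.rsid_or_marker, r.outcome, r.stratum, r.adjusted) for r in results]
        assert keys == sorted(
            keys,
            key=lambda k: (
                cohort.rsids.index(k[0]),
                OUTCOME_NAMES.index(k[1]),
                STRATA.index(k[2]),
                k[3],
            ),
        )

    def test_subject_permutation_leaves_cells_unchanged(self, study_cohort):
        cohort, _ = study_cohort
        from sscpgx.cohort_model import Cohort

        shuffled = Cohort(
            list(reversed(cohort.subjects)), dict(cohort.genotypes), list(cohort.panel)
        )
        a = odds_ratio_for_cell(cohort, "rs4149056", "pf", "MTX", True)
        b = odds_ratio_for_cell(shuffled, "rs4149056", "pf", "MTX", True)
        assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-9)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_bh_column_is_supplementary_and_valid(self, study_cohort):
        cohort, _ = study_cohort
        df = results_to_frame(run_association_grid(cohort))
        est = df[df["estimable"]]
        assert (est["p_bh"] >= est["p_value"] - 1e-12).all()
        assert df.loc[~df["estimable"], "p_bh"].isna().all()


class TestForestData:
    def test_only_estimable_cells_exported(self, study_cohort):
        cohort, _ = study_cohort
        results = run_association_grid(cohort)
        df = forest_plot_data(results)
        assert len(df) == sum(r.estimable for r in results)
        assert (df["null_line"] == 1.0).all()

    def test_empty_export_keeps_header(self):
        df = forest_plot_data([])
        assert list(df.columns)[:3] == ["marker", "outcome", "stratum"]
        assert df.empty

    def test_protective_or_left_of_null(self):
        from sscpgx.association import AssociationResult

        r = AssociationResult(
            "rs", "pf", "all", 50, 20, 0.6, 0.3, 1.2, 0.2, False, (), True
        )
        df = forest_plot_data([r])
        assert df.loc[0, "odds_ratio"] < df.loc[0, "null_line"] < df.loc[0, "ci_high"]
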