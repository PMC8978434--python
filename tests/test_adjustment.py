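"""Unit and property tests for the confounding-adjustment estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.base import clone

from temsim.adjustment import (
    AdjustmentModel,
    AdjustmentSpec,
    EstimationError,
    Method,
    TEMEstimator,
    covariate_set,
    estimate_all,
    estimate_effects,
    fit_propensity,
    iptw_weights,
    nn_match,
)
from temsim.adjustment import _fit_logit
from temsim.dgp import DGPCoefficients, generate_cohort

XCOLS = ["X1", "X2", "X3", "X4", "X5", "X6"]
ZEROS6 = (0.0,) * 6

ALL_SPECS = [AdjustmentSpec(me, mo) for me in Method for mo in AdjustmentModel]


class TestCovariateSet:
    @pytest.mark.parametrize("model, n_terms", [
        (AdjustmentModel.MAIN_EFFECTS, 7),
        (AdjustmentModel.ONE_INTERACTION, 8),
        (AdjustmentModel.ALL_INTERACTIONS, 13),
        (AdjustmentModel.STRATIFIED, 6),
    ])
    def test_term_counts(self, model, n_terms):
        assert len(covariate_set(model)) == n_terms

    def test_interaction_terms_named(self):
        terms = covariate_set("c")
        assert {f"M:X{j}" for j in range(1, 7)} <= set(terms)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            covariate_set("z")


class TestFitPropensity:
    def test_null_model_limit(self):
        """Treatment independent of all covariates: slopes shrink to zero and
        fitted scores cluster at the raw treatment rate."""
        rng = np.random.default_rng(0)
        n = 20_000
        df = pd.DataFrame(rng.standard_normal((n, 6)), columns=XCOLS)
        df[["X4", "X5", "X6"]] = rng.binomial(1, 0.3, (n, 3))
        df["M"] = rng.binomial(1, 0.5, n)
        df["T"] = rng.binomial(1, 0.4, n)
        fit = fit_propensity(df, "a")
        assert fit.converged
        assert np.abs(fit.coefficients[2:]).max() < 0.05
        assert np.allclose(fit.ps, df["T"].mean(), atol=0.05)

    def test_two_cell_closed_form(self):
        """An 8-row grouped design with one binary predictor has the exact
        logistic MLE ps = the within-cell treatment proportions."""
        x4 = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        t = np.array([1, 0, 0, 0, 1, 1, 1, 0])  # rates 1/4 and 3/4
        exog = np.column_stack([np.ones(8), x4])
        ps, params, conv = _fit_logit(t, exog)
        assert conv
        np.testing.assert_allclose(ps[x4 == 0], 0.25, atol=1e-6)
        np.testing.assert_allclose(ps[x4 == 1], 0.75, atol=1e-6)
        np.testing.assert_allclose(params[0], np.log(0.25 / 0.75), atol=1e-6)

    def test_all_interactions_equals_stratified(self, cohort):
        """A logistic model with M main effect plus all M x Xj products IS the
        stratified model, so the fitted scores coincide."""
        df = cohort.to_frame()
        ps_c = fit_propensity(df, "c").ps
        ps_d = fit_propensity(df, "d").ps
        np.testing.assert_allclose(ps_c, ps_d, rtol=1e-6, atol=1e-8)

    def test_single_arm_cohort_rejected(self, cohort):
        df = cohort.to_frame().copy()
        df["T"] = 1
        with pytest.raises(EstimationError):
            fit_propensity(df, "a")

    def test_monotone_in_positive_coefficient(self, cohort):
        """Raising a covariate whose fitted slope is positive raises the
        fitted propensity score."""
        fit = fit_propensity(cohort.to_frame(), "a")
        coefs = fit.coefficients  # [const, M, X1..X6]
        base = np.zeros(8)
        base[0] = 1.0
        for j in range(2, 8):
            hi = base.copy()
            hi[j] = 1.0
            diff = expit(hi @ coefs) - expit(base @ coefs)
            assert np.sign(diff) == np.sign(coefs[j])


class TestIPTWWeights:
    def test_pointwise_values(self):
        w = iptw_weights(np.array([0.5, 0.2]), np.array([1, 0]))
        np.testing.assert_allclose(w, [2.0, 1.25])

    def test_boundary_scores_rejected(self):
        with pytest.raises(ValueError):
            iptw_weights(np.array([0.0, 0.5]), np.array([1, 0]))

    def test_horvitz_thompson_mass(self, default_coeffs):
        """Weights reconstruct the full cohort in each arm: the weighted arm
        sizes are close to n (Horvitz-Thompson identity, checked on fitted
        scores at large n)."""
        coeffs = default_coeffs.with_(n=20_000)
        c = generate_cohort(coeffs, 11)
        fit = fit_propensity(c.to_frame(), "a")
        w = iptw_weights(fit, c.T)
        n = len(c)
        assert w[c.T == 1].sum() == pytest.approx(n, rel=0.05)
        assert w[c.T == 0].sum() == pytest.approx(n, rel=0.05)


class TestNNMatch:
    def test_nearest_is_selected(self):
        ps = np.array([0.6, 0.55, 0.70])
        t = np.array([1, 0, 0])
        res = nn_match(ps, t)
        assert res.control_idx.tolist() == [1]

    def test_with_replacement_reuses_control(self):
        ps = np.array([0.3, 0.6, 0.5])
        t = np.array([1, 1, 0])
        res = nn_match(ps, t)
        assert res.control_idx.tolist() == [2, 2]
        rows, counts = res.control_weights()
        assert rows.tolist() == [2] and counts.tolist() == [2]

    def test_tie_breaks_to_lowest_row_index(self):
        ps = np.array([0.5, 0.45, 0.55])
        t = np.array([1, 0, 0])
        res = nn_match(ps, t)
        assert res.control_idx.tolist() == [1]

    def test_no_controls_rejected(self):
        with pytest.raises(EstimationError):
            nn_match(np.array([0.5]), np.array([1]))

    def test_each_treated_matched_exactly_once(self, cohort):
        fit = fit_propensity(cohort.to_frame(), "a")
        res = nn_match(fit, cohort.T)
        assert sorted(res.treated_idx) == sorted(np.flatnonzero(cohort.T == 1))
        assert len(res.control_idx) == len(res.treated_idx)
        assert np.isin(res.control_idx, np.flatnonzero(cohort.T == 0)).all()

    def test_matches_brute_force_oracle(self, rng):
        """Vectorised matcher agrees with an O(n^2) argmin with the
        min-distance-then-lowest-index tie rule, including duplicate scores."""
        for trial in range(20):
            n = 30
            # coarse grid of scores forces frequent exact ties
            ps = rng.integers(0, 8, n) / 8.0 + 0.05
            t = rng.integers(0, 2, n)
            if t.min() == t.max():
                continue
            res = nn_match(ps, t)
            controls = np.flatnonzero(t == 0)
            for treated_row, matched in zip(res.treated_idx, res.control_idx):
                d = np.abs(ps[controls] - ps[treated_row])
                best = controls[d == d.min()].min()
                assert matched == best


class TestEstimateEffects:
    def test_noiseless_unconfounded_cohort_exact(self):
        """With no confounder effects and no noise every method and model
        returns the generating subgroup effects exactly."""
        c = DGPCoefficients(alpha_x=ZEROS6, alpha_m=0.0, alpha_mx1=0.0,
                            beta_x=ZEROS6, beta_mx1=0.0, beta_tm=0.3,
                            sigma_e1=0.0, sigma_y=0.0)
        cohort = generate_cohort(c, 8)
        for spec in ALL_SPECS:
            est = estimate_effects(cohort, spec)
            assert est.bt_m0 == pytest.approx(1.5, abs=1e-7), spec
            assert est.bt_m1 == pytest.approx(1.8, abs=1e-7), spec
            assert est.btm == pytest.approx(0.3, abs=1e-7), spec

    def test_tem_identity_all_combinations(self, cohort):
        for spec, est in estimate_all(cohort).items():
            assert est is not None
            assert est.btm == pytest.approx(est.bt_m1 - est.bt_m0, abs=1e-10)

    @pytest.mark.parametrize("method", [Method.REGRESSION, Method.IPTW])
    def test_all_interactions_equals_stratified_estimates(self, cohort, method):
        """Adjustment models c and d are the same model in different
        parametrisations for regression and IPTW, so the point estimates
        agree to optimizer tolerance."""
        ec = estimate_effects(cohort, AdjustmentSpec(method, "c"))
        ed = estimate_effects(cohort, AdjustmentSpec(method, "d"))
        assert ec.btm == pytest.approx(ed.btm, rel=1e-6, abs=1e-8)
        assert ec.bt_m1 == pytest.approx(ed.bt_m1, rel=1e-6)
        assert ec.bt_m0 == pytest.approx(ed.bt_m0, rel=1e-6)

    def test_empty_stratum_flagged_as_failure(self, cohort):
        df = cohort.to_frame().copy()
        df.loc[df["M"] == 1, "T"] = 1  # no untreated subjects with M=1
        with pytest.raises(EstimationError):
            estimate_effects(df, AdjustmentSpec("regression", "d"))
        res = estimate_all(df, [AdjustmentSpec("iptw", "d")])
        assert res[AdjustmentSpec("iptw", "d")] is None

    def test_shared_ps_matches_independent_fits(self, cohort):
        """estimate_all (shared propensity fits) reproduces the one-at-a-time
        estimates exactly."""
        shared = estimate_all(cohort)
        for spec in [AdjustmentSpec("ps_covariate", "b"), AdjustmentSpec("ps_matching", "d")]:
            single = estimate_effects(cohort, spec)
            assert shared[spec].btm == pytest.approx(single.btm, abs=1e-12)


class TestTEMEstimatorAPI:
    def test_fitted_attributes_and_clone(self, cohort):
        df = cohort.to_frame()
        est = TEMEstimator(method="ps_covariate", adjustment_model="b")
        est.fit(df[["T", "M", *XCOLS]], df["Y"])
        assert est.tem_ == pytest.approx(est.effect_m1_ - est.effect_m0_, abs=1e-10)
        assert est.se_tem_ > 0 and est.converged_
        assert est.propensity_ is not None
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        assert not hasattr(cloned, "tem_")

    def test_get_set_params_round_trip(self):
        est = TEMEstimator()
        est.set_params(method="iptw", adjustment_model="d")
        assert est.get_params()["method"] == "iptw"

    def test_arbitrary_confounder_count(self, rng):
        n = 600
        df = pd.DataFrame({"treat": rng.integers(0, 2, n),
                           "mod": rng.integers(0, 2, n),
                           "age": rng.normal(50, 10, n),
                           "bmi": rng.normal(25, 4, n)})
        y = 1.0 * df["treat"] + 0.02 * df["age"] + rng.normal(0, 0.5, n)
        est = TEMEstimator(method="regression", adjustment_model="c",
                           treatment="treat", moderator="mod")
        est.fit(df, y)
        assert est.confounder_names_ == ["age", "bmi"]
        assert abs(est.effect_m0_ - 1.0) < 0.3

    @pytest.mark.parametrize("corrupt", ["nonbinary_t", "missing_col", "nonfinite"])
    def test_input_validation(self, cohort, corrupt):
        df = cohort.to_frame()[["T", "M", *XCOLS]].copy()
        y = cohort.Y.copy()
        if corrupt == "nonbinary_t":
            df.loc[0, "T"] = 2
        elif corrupt == "missing_col":
            df = df.drop(columns=["M"])
        else:
            y[0] = np.nan
        with pytest.raises((ValueError, KeyError)):
            TEMEstimator(confounders=XCOLS).fit(df, y)
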