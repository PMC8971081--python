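"""MSM fitting, per-DDD conversion, window combination, regimen curves."""

import numpy as np
import pandas as pd
import pytest

import wcemsm as w
from wcemsm.cox_wce import FitResult
from wcemsm.exposure_history import HIGH_MEDIAN, LOW_MEDIAN
from wcemsm.msm_pipeline import (
    MSM_NUMERIC,
    _regimen_proportions,
    combine_msm_windows,
    convert_or_per_ddd,
    fit_msm,
)


def synthetic_fit(coefs: dict, cov=None):
    terms = ["intercept"] + MSM_NUMERIC
    params = np.array([coefs.get(t, 0.0) for t in terms])
    c = np.eye(len(terms)) * 0.01 if cov is None else cov
    return FitResult(terms=terms, params=params, cov=c, cov_robust=c,
                     n_rows=10, n_events=2, converged=True, loglik=0.0,
                     meta={"categorical_levels": {}, "quarter_bins": {}})


class TestPerDddConversion:
    def test_exact_linearity_recovers_slope(self):
        s = -0.4
        fit = synthetic_fit({"met_p_low_w2": LOW_MEDIAN * s,
                             "met_p_high_w2": HIGH_MEDIAN * s})
        out = convert_or_per_ddd(fit, "w2")
        assert out["estimate"] == pytest.approx(np.exp(s))

    def test_null_gives_or_one(self):
        out = convert_or_per_ddd(synthetic_fit({}), "w1")
        assert out["estimate"] == pytest.approx(1.0)
        assert out["ci_low"] < 1.0 < out["ci_high"]

    def test_delta_method_interval_by_hand(self):
        bl, bh = 0.10, 0.45
        vl, vh, c = 0.04, 0.09, 0.01
        terms = ["intercept", "met_p_low_w1", "met_p_high_w1"]
        cov = np.zeros((3, 3))
        cov[1:, 1:] = [[vl, c], [c, vh]]
        fit = FitResult(terms=terms, params=np.array([0.0, bl, bh]), cov=cov,
                        cov_robust=cov, n_rows=10, n_events=2, converged=True,
                        loglik=0.0)
        out = convert_or_per_ddd(fit, "w1")
        denom = LOW_MEDIAN**2 + HIGH_MEDIAN**2
        a = np.array([LOW_MEDIAN, HIGH_MEDIAN]) / denom
        slope = a @ [bl, bh]
        se = np.sqrt(a @ [[vl, c], [c, vh]] @ a)
        assert out["log_estimate"] == pytest.approx(slope)
        assert out["se"] == pytest.approx(se)
        assert out["ci_low"] == pytest.approx(np.exp(slope - 1.959964 * se), rel=1e-6)

    def test_high_only_variant(self):
        fit = synthetic_fit({"met_p_high_w3": 0.3})
        out = convert_or_per_ddd(fit, "w3", method="high")
        assert out["log_estimate"] == pytest.approx(0.3 / HIGH_MEDIAN)

    def test_missing_terms_raise(self):
        fit = synthetic_fit({})
        fit.terms = ["intercept"]
        fit.params = np.zeros(1)
        with pytest.raises(KeyError):
            convert_or_per_ddd(fit, "w1")


class TestCombineWindows:
    def test_null_product_is_one(self):
        out = combine_msm_windows(synthetic_fit({}))
        assert out["estimate"] == pytest.approx(1.0)

    def test_product_and_monotonicity(self):
        base = {"met_p_low_w2": 0.05, "met_p_high_w2": 0.15,
                "met_p_low_w3": -0.02, "met_p_high_w3": -0.06}
        out = combine_msm_windows(synthetic_fit(base))
        w2 = convert_or_per_ddd(synthetic_fit(base), "w2")["estimate"]
        w3 = convert_or_per_ddd(synthetic_fit(base), "w3")["estimate"]
        assert out["estimate"] == pytest.approx(w2 * w3)
        bumped = dict(base, met_p_high_w2=0.30)
        assert combine_msm_windows(synthetic_fit(bumped))["estimate"] > out["estimate"]


def test_all_ones_weights_equal_unweighted(small_rows):
    f0 = fit_msm(small_rows, cluster=False)
    f1 = fit_msm(small_rows, weights=np.ones(len(small_rows)), cluster=False)
    assert np.allclose(f0.params, f1.params, atol=1e-10)


def test_weight_key_mismatch_raises(small_rows):
    wts = pd.DataFrame({"subject_id": [-1], "quarter": [0], "weight_truncated": [1.0]})
    with pytest.raises(ValueError, match="weights missing"):
        fit_msm(small_rows, weights=wts)


def test_msm_matches_statsmodels_weighted(small_rows):
    """Weighted pooled logistic against statsmodels GLM with var_weights."""
    import statsmodels.api as sm
    from wcemsm.cox_wce import build_design

    rng = np.random.default_rng(8)
    wts = rng.uniform(0.5, 2.0, len(small_rows))
    fit = fit_msm(small_rows, weights=wts, cluster=False,
                  numeric=MSM_NUMERIC, categorical=["age_group"])
    X, names, _ = build_design(small_rows, MSM_NUMERIC, ["age_group"])
    res = sm.GLM(small_rows.event.to_numpy(float), X,
                 family=sm.families.Binomial(), var_weights=wts).fit(maxiter=200, tol=1e-12)
    assert np.allclose(fit.params, res.params, atol=1e-8)


class TestRegimenCurve:
    def test_window_fill_fractions(self):
        # at the index quarter no history exists yet
        assert _regimen_proportions(8, 8, "w1") == 0.0
        # one quarter later, one of four w1 lags is on-regimen
        assert _regimen_proportions(9, 8, "w1") == pytest.approx(1 / 4)
        # far from start, every window saturates
        assert _regimen_proportions(60, 8, "w1") == 1.0
        assert _regimen_proportions(60, 8, "w2") == 1.0
        assert _regimen_proportions(60, 8, "w3") == 1.0
        # w3 (lags 17-28) starts filling 18 quarters after the index
        assert _regimen_proportions(8 + 17, 8, "w3") == pytest.approx(1 / 12)

    def test_zero_hazard_flat_curve(self):
        fit = synthetic_fit({"intercept": -30.0})
        curve = w.project_regimen_curve(fit, "high", {}, horizon=10)
        assert np.allclose(curve.event_free, 1.0, atol=1e-8)

    def test_constant_hazard_geometric(self):
        h = 0.01
        fit = synthetic_fit({"intercept": float(np.log(h / (1 - h)))})
        curve = w.project_regimen_curve(fit, "none", {}, horizon=20)
        assert np.allclose(curve.event_free, (1 - h) ** np.arange(21), rtol=1e-10)

    def test_nonincreasing_for_fitted_model(self, small_rows):
        fit = fit_msm(small_rows, cluster=False)
        profile = {"age_group": small_rows.age_group.iloc[0],
                   "ses": small_rows.ses.iloc[0],
                   "ethnicity": small_rows.ethnicity.iloc[0]}
        curve = w.project_regimen_curve(fit, "high", profile, horizon=30)
        assert curve.event_free[0] == 1.0
        assert np.all(np.diff(curve.event_free) <= 0)
        assert np.all((0 <= curve.event_free) & (curve.event_free <= 1))

    def test_unknown_profile_level_raises(self, small_rows):
        fit = fit_msm(small_rows, cluster=False)
        with pytest.raises(KeyError):
            w.project_regimen_curve(fit, "high", {"age_group": "not-a-group"})
        with pytest.raises(KeyError):
            w.project_regimen_curve(fit, "mega", {})


def test_unconfounded_dgp_weighted_equals_unweighted():
    """When prescribing ignores the biomarkers, weighting changes nothing
    beyond Monte-Carlo noise."""
    import dataclasses
    diffs = []
    for s in range(3):
        cfg = w.null_effect_config(seed=100 + s)
        cfg.n_subjects = 1500
        cfg.dose_logit_params = dataclasses.replace(
            cfg.dose_logit_params, hba1c_coef_low=0.0, hba1c_coef_high=0.0)
        panel = w.simulate_cohort(cfg)
        rows = w.build_analysis_rows(panel)
        covs = w.build_weight_covariates(panel)
        den = w.fit_weight_model(covs)
        num = w.fit_numerator_model(covs)
        wts = w.compute_weights(covs, den, num)
        fw = fit_msm(rows, weights=wts, cluster=False)
        fu = fit_msm(rows, cluster=False)
        dw = convert_or_per_ddd(fw, "w1")
        du = convert_or_per_ddd(fu, "w1")
        diffs.append((dw["log_estimate"] - du["log_estimate"], du["se"]))
    mean_diff = np.mean([d for d, _ in diffs])
    scale = np.mean([s for _, s in diffs])
    assert abs(mean_diff) < scale


def test_run_msm_analysis_strategies_agree_without_missingness(small_cohort):
    """With nothing missing, indicator, LOCF and MI give identical estimates."""
    fits = {}
    for strat in ("none", "indicator", "locf", "mi"):
        res = w.run_msm_analysis(small_cohort, strategy=strat, weighted=False,
                                 m=2, seed=0, cluster=False)
        fits[strat] = res["fit"]
    base = fits["none"].params
    for strat in ("indicator", "locf", "mi"):
        assert np.allclose(fits[strat].params, base, atol=1e-8), strat


def test_run_full_pipeline_deterministic(tmp_path):
    from wcemsm.cli_report import RunConfig, render_report

    cfg = w.default_dgp_config(seed=6)
    cfg.n_subjects = 400
    rc = RunConfig(dgp=cfg, seed=6, strategy="indicator", horizon=12)
    r1 = w.run_full_pipeline(rc)
    r2 = w.run_full_pipeline(rc)
    assert render_report(r1) == render_report(r2)
    assert np.allclose(r1["msm_weighted"]["fit"].params,
                       r2["msm_weighted"]["fit"].params)
    for regimen in ("none", "high"):
        ef = r1["curves"][regimen].event_free
        assert ef[0] == 1.0 and np.all(np.diff(ef) <= 0)
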