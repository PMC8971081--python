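"""Indicator, LOCF and sequential-imputation strategies; Rubin pooling."""

import numpy as np
import pandas as pd
import pytest

import wcemsm as w
from wcemsm.cox_wce import FitResult
from wcemsm.exposure_history import DataError
from wcemsm.ipw_weights import build_weight_covariates
from conftest import toy_panel


class TestIndicator:
    def test_fully_observed_unchanged(self, small_cohort):
        covs = build_weight_covariates(small_cohort)
        out = w.apply_missing_indicator(covs)
        assert len(out) == len(covs)
        for col in ("hba1c0", "glucose0", "hba1c_avg3", "glucose_avg3"):
            assert np.allclose(out[col], covs[col])
            assert (out[f"{col}_missing"] == 0).all()

    def test_hand_mean_fill(self):
        covs = pd.DataFrame({"hba1c_avg3": [6.0, np.nan, 8.0],
                             "glucose_avg3": [100.0, 110.0, 120.0]})
        out = w.apply_missing_indicator(covs)
        assert out.hba1c_avg3.tolist() == [6.0, 7.0, 8.0]
        assert out.hba1c_avg3_missing.tolist() == [0.0, 1.0, 0.0]
        assert out.glucose_avg3_missing.tolist() == [0.0, 0.0, 0.0]

    def test_entirely_missing_column_raises(self):
        covs = pd.DataFrame({"hba1c_avg3": [np.nan, np.nan]})
        with pytest.raises(DataError):
            w.apply_missing_indicator(covs)

    def test_preserves_rows_with_missingness(self, missing_cohort):
        covs = build_weight_covariates(missing_cohort)
        out = w.apply_missing_indicator(covs)
        assert len(out) == len(covs)
        assert not out[["hba1c_avg3", "glucose_avg3"]].isna().any().any()
        # observed values untouched
        obs = covs.hba1c_avg3.notna()
        assert np.allclose(out.hba1c_avg3[obs], covs.hba1c_avg3[obs])


class TestLocf:
    def test_series_carried_forward(self):
        panel = toy_panel([(1, q, 0.0, q >= 2, False, False) for q in range(3)])
        panel.loc[panel.quarter > 0, ["hba1c", "glucose"]] = np.nan
        out = w.apply_locf(panel)
        assert out.hba1c.tolist() == [7.0, 7.0, 7.0]

    def test_never_observed_subject_dropped(self):
        panel = toy_panel([(1, q, 0.0, q >= 2, False, False) for q in range(4)]
                          + [(2, q, 0.0, q >= 2, False, False) for q in range(4)])
        panel.loc[panel.subject_id == 2, "hba1c"] = np.nan
        out = w.apply_locf(panel)
        assert out.subject_id.unique().tolist() == [1]
        assert out.attrs["locf_dropped"] == [2]

    def test_fully_observed_unchanged(self, small_cohort):
        out = w.apply_locf(small_cohort)
        pd.testing.assert_frame_equal(
            out, small_cohort.reset_index(drop=True), check_dtype=False
        )

    def test_drops_only_late_starters(self, missing_cohort):
        out = w.apply_locf(missing_cohort)
        kept = set(out.subject_id)
        idx = missing_cohort[missing_cohort.at_risk].groupby("subject_id").quarter.min()
        for sid, first_risk in idx.items():
            pre = missing_cohort[(missing_cohort.subject_id == sid)
                                 & (missing_cohort.quarter < first_risk)]
            fully_observed_pre = pre.hba1c.notna().any() and pre.glucose.notna().any()
            assert (sid in kept) == fully_observed_pre
        assert not out[["hba1c", "glucose"]].isna().any().any()


class TestSequentialImpute:
    def test_seeded_determinism(self, missing_cohort):
        a = w.sequential_impute(missing_cohort, m=2, seed=4)
        b = w.sequential_impute(missing_cohort, m=2, seed=4)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        c = w.sequential_impute(missing_cohort, m=2, seed=5)
        assert not a[0].equals(c[0])

    def test_fully_observed_identity(self, small_cohort):
        panels = w.sequential_impute(small_cohort, m=3, seed=0)
        for p in panels:
            pd.testing.assert_frame_equal(
                p, small_cohort.sort_values(["subject_id", "quarter"]).reset_index(drop=True),
                check_dtype=False,
            )

    def test_observed_values_untouched_and_complete(self, missing_cohort):
        panels = w.sequential_impute(missing_cohort, m=2, seed=1)
        base = missing_cohort.sort_values(["subject_id", "quarter"]).reset_index(drop=True)
        for p in panels:
            assert not p[["hba1c", "glucose"]].isna().any().any()
            obs = base.hba1c.notna()
            assert np.allclose(p.hba1c[obs], base.hba1c[obs])
        # imputations differ between draws
        assert not np.allclose(panels[0].hba1c, panels[1].hba1c)

    def test_imputations_match_observed_distribution(self, missing_cohort):
        """MCAR imputation should roughly reproduce the observed spread."""
        p = w.sequential_impute(missing_cohort, m=2, seed=2)[0]
        base = missing_cohort.sort_values(["subject_id", "quarter"]).reset_index(drop=True)
        miss = base.hba1c.isna()
        assert abs(p.hba1c[miss].mean() - base.hba1c[~miss].mean()) < 0.2
        assert p.hba1c[miss].std() < 2.0 * base.hba1c[~miss].std()


class TestPoolRubin:
    @staticmethod
    def fit_of(params, var):
        k = len(params)
        cov = np.diag(var)
        return FitResult(terms=[f"b{i}" for i in range(k)],
                         params=np.asarray(params, float), cov=cov,
                         cov_robust=cov, n_rows=5, n_events=1,
                         converged=True, loglik=-1.0)

    def test_single_fit_identity(self):
        f = self.fit_of([0.5, -0.2], [0.01, 0.02])
        pooled = w.pool_rubin([f])
        assert np.allclose(pooled.params, f.params)
        assert np.allclose(pooled.cov, f.cov)

    def test_identical_fits_no_between_variance(self):
        f = self.fit_of([0.5], [0.01])
        pooled = w.pool_rubin([f, f, f])
        assert pooled.params[0] == pytest.approx(0.5)
        assert pooled.cov[0, 0] == pytest.approx(0.01)

    def test_hand_computed_rubin_formulas(self):
        ests = [0.40, 0.55, 0.46]
        vars_ = [0.010, 0.012, 0.011]
        fits = [self.fit_of([e], [v]) for e, v in zip(ests, vars_)]
        pooled = w.pool_rubin(fits)
        qbar = np.mean(ests)
        within = np.mean(vars_)
        between = np.var(ests, ddof=1)
        total = within + (1 + 1 / 3) * between
        assert pooled.params[0] == pytest.approx(qbar)
        assert pooled.cov[0, 0] == pytest.approx(total)

    def test_mismatched_terms_raise(self):
        a = self.fit_of([0.1], [0.01])
        b = self.fit_of([0.1], [0.01])
        b.terms = ["other"]
        with pytest.raises(ValueError):
            w.pool_rubin([a, b])
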