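"""Missing-biomarker strategies for the weighting pipeline.

Quarterly HbA1c and glucose values are missing for a substantial share of
subject-quarters (roughly 25-50% and 20-25% respectively in the kind of
claims data this pipeline targets).  Three strategies make the weighting
covariates complete:

* **missing-value indicators** -- each modelled biomarker covariate
  (baseline value and previous-3-quarter average) is filled with its
  observed-data mean and gains a binary missingness indicator that enters
  the weighting model; no rows are dropped;
* **last value carried forward (LOCF)** -- each missing quarterly value is
  replaced by the subject's most recent observed value; subjects with no
  observed value before their first at-risk quarter are dropped, so the
  analysed cohort shrinks;
* **time-sequential multiple imputation** -- quarters are imputed in time
  order from a normal linear model (previous quarter's value, current dose
  class, baseline covariates, quarter), with proper parameter and residual
  draws per imputation; estimates across the ``m`` completed panels are
  pooled with Rubin's rules.

Observed values are never altered by any strategy.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cox_wce import FitResult
from .exposure_history import DataError

log = logging.getLogger(__name__)

BIOMARKERS = ("hba1c", "glucose")
COVARIATE_COLUMNS = ("hba1c0", "glucose0", "hba1c_avg3", "glucose_avg3")


def apply_missing_indicator(covs: pd.DataFrame) -> pd.DataFrame:
    """Mean-fill the biomarker covariates and attach missingness indicators.

    Operates on the weight-covariate frame: each of ``hba1c0``,
    ``glucose0``, ``hba1c_avg3`` and ``glucose_avg3`` is filled with the
    mean of its observed values and gains an ``<name>_missing`` 0/1 column.
    Row count is preserved exactly.
    """
    out = covs.copy()
    for col in COVARIATE_COLUMNS:
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(float)
        miss = np.isnan(vals)
        if miss.all():
            raise DataError(f"covariate {col!r} is entirely missing; cannot mean-fill")
        out[f"{col}_missing"] = miss.astype(float)
        if miss.any():
            out[col] = np.where(miss, np.nanmean(vals), vals)
    return out


def _first_at_risk(panel: pd.DataFrame) -> pd.Series:
    at_risk = panel[panel["at_risk"].astype(bool)]
    return at_risk.groupby("subject_id")["quarter"].min()


def apply_locf(panel: pd.DataFrame) -> pd.DataFrame:
    """Carry the last observed biomarker value forward; drop late starters.

    A subject is dropped when either biomarker has no observed value before
    the subject's first at-risk quarter (for subjects who never reach an
    at-risk quarter: no observed value at all).  For kept subjects, quarters
    preceding the first observation are back-filled with that first observed
    value so that the weighting model has complete rows from quarter 0.
    Dropped subject ids are recorded in ``panel.attrs['locf_dropped']``.
    """
    panel = panel.sort_values(["subject_id", "quarter"], kind="stable")
    first_risk = _first_at_risk(panel)
    subjects = panel["subject_id"].unique()
    drop = set()
    for col in BIOMARKERS:
        first_obs = panel[~panel[col].isna()].groupby("subject_id")["quarter"].min()
        for sid in subjects:
            fo = first_obs.get(sid, np.inf)
            if sid in first_risk.index:
                if fo >= first_risk[sid]:
                    drop.add(sid)
            elif not np.isfinite(fo):  # never at risk and never observed
                drop.add(sid)

    kept = panel[~panel["subject_id"].isin(drop)].copy()
    grouped = kept.groupby("subject_id", sort=False)
    for col in BIOMARKERS:
        kept[col] = grouped[col].ffill()
        kept[col] = kept.groupby("subject_id", sort=False)[col].bfill()
        base = f"{col}0"
        if kept[base].isna().any():
            first_val = kept.groupby("subject_id", sort=False)[col].transform("first")
            kept[base] = kept[base].fillna(first_val)
    kept.attrs["locf_dropped"] = sorted(drop)
    if drop:
        log.info("LOCF dropped %d subjects with no pre-index biomarker observation", len(drop))
    return kept.reset_index(drop=True)


def _imputation_design(panel: pd.DataFrame, prev: np.ndarray) -> np.ndarray:
    met = panel["metformin_ddd"].to_numpy(float)
    blocks = [
        np.ones(len(panel)),
        prev,
        ((met > 0) & (met < 0.5)).astype(float),
        (met >= 0.5).astype(float),
        panel["quarter"].to_numpy(float),
    ]
    for col in ("age_group", "ethnicity", "ses"):
        levels = sorted(pd.unique(panel[col]).tolist())
        for lv in levels[1:]:
            blocks.append((panel[col].to_numpy() == lv).astype(float))
    return np.column_stack(blocks)


def sequential_impute(panel: pd.DataFrame, m: int = 5, seed: int = 0) -> list:
    """Time-sequential multiple imputation of the quarterly biomarkers.

    For each biomarker a normal linear model is fitted on the observed rows
    (previous-quarter value -- the pre-treatment baseline at quarter 0 --
    plus dose class, quarter and baseline covariates).  Per imputation, the
    residual variance is drawn from its scaled inverse chi-square posterior
    and the coefficients from their normal posterior; quarters are then
    filled in time order so imputed values feed the next quarter's
    predictor.  Returns ``m`` completed panels; a fully observed panel
    yields ``m`` identical copies.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    rng = np.random.default_rng([int(seed), 0x1337])
    panel = panel.sort_values(["subject_id", "quarter"], kind="stable").reset_index(drop=True)
    if panel[["hba1c0", "glucose0"]].isna().any().any():
        raise DataError("sequential imputation requires complete baseline biomarker columns")

    nq = int(panel["quarter"].max()) + 1
    prev_idx = np.arange(len(panel)) - 1
    is_first = panel["quarter"].to_numpy(int) == 0

    models = {}
    for col in BIOMARKERS:
        y = panel[col].to_numpy(float)
        prev_obs = np.where(is_first, panel[f"{col}0"].to_numpy(float), y[prev_idx])
        fit_rows = ~np.isnan(y) & ~np.isnan(prev_obs)
        X = _imputation_design(panel, np.nan_to_num(prev_obs))
        Xf, yf = X[fit_rows], y[fit_rows]
        k = X.shape[1]
        if fit_rows.sum() < k + 2:
            raise DataError(
                f"too few observed rows ({int(fit_rows.sum())}) to fit the "
                f"imputation model for {col!r} ({k} parameters)"
            )
        beta, _, _, _ = np.linalg.lstsq(Xf, yf, rcond=None)
        resid = yf - Xf @ beta
        df = fit_rows.sum() - k
        rss = float(resid @ resid)
        xtx_inv = np.linalg.pinv(Xf.T @ Xf)
        models[col] = (beta, rss, df, xtx_inv)

    quarter = panel["quarter"].to_numpy(int)
    # the design's only time-sequential column is the previous value (index 1),
    # so precompute the contribution of everything else once
    X_static = _imputation_design(panel, np.zeros(len(panel)))
    panels = []
    for _ in range(m):
        out = panel.copy()
        for col in BIOMARKERS:
            beta_hat, rss, df, xtx_inv = models[col]
            y = out[col].to_numpy(float).copy()
            if not np.isnan(y).any():
                continue
            sigma2 = rss / rng.chisquare(df)
            chol = np.linalg.cholesky(sigma2 * xtx_inv + 1e-12 * np.eye(len(beta_hat)))
            beta = beta_hat + chol @ rng.standard_normal(len(beta_hat))
            base_pred = X_static @ beta  # prev-value column is zero here
            base = out[f"{col}0"].to_numpy(float)
            for q in range(nq):
                miss = (quarter == q) & np.isnan(y)
                if not miss.any():
                    continue
                prev = np.where(is_first[miss], base[miss], y[prev_idx[miss]])
                y[miss] = (base_pred[miss] + beta[1] * prev
                           + rng.normal(0.0, np.sqrt(sigma2), int(miss.sum())))
            out[col] = y
        panels.append(out)
    return panels


def pool_rubin(fits: list) -> FitResult:
    """Combine per-imputation fits with Rubin's rules on the coefficient scale.

    Pooled estimate = mean of coefficients; pooled covariance = mean
    within-imputation covariance + (1 + 1/m) x between-imputation
    covariance, applied to both the model-based and the cluster-robust
    covariance.
    """
    if len(fits) == 0:
        raise ValueError("no fits to pool")
    terms = fits[0].terms
    for f in fits[1:]:
        if f.terms != terms:
            raise ValueError("cannot pool fits with mismatched term lists")
    m = len(fits)
    params = np.stack([f.params for f in fits])
    pooled = params.mean(axis=0)
    if m > 1:
        centred = params - pooled
        between = centred.T @ centred / (m - 1)
    else:
        between = np.zeros((len(terms), len(terms)))
    cov = np.mean([f.cov for f in fits], axis=0) + (1 + 1 / m) * between
    cov_robust = np.mean([f.cov_robust for f in fits], axis=0) + (1 + 1 / m) * between
    return FitResult(
        terms=list(terms),
        params=pooled,
        cov=cov,
        cov_robust=cov_robust,
        n_rows=fits[0].n_rows,
        n_events=fits[0].n_events,
        converged=all(f.converged for f in fits),
        loglik=float(np.mean([f.loglik for f in fits])),
        meta={"m": m, **fits[0].meta},
    )
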