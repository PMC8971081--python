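"""Marginal structural model fitting, per-DDD conversion and projection.

The MSM is a pooled logistic regression on the at-risk person-period rows,
fitted in the population reweighted by the stabilized, truncated IPWs (or
unweighted, for comparison).  Metformin exposure enters as six covariates:
the proportions of quarters spent in the low and high dose class within
each of the three look-back windows.  Adjustment covariates are baseline
age group, ethnicity and socioeconomic status; quarter (time since
diagnosis) enters as a factor in place of a baseline hazard.

Category log-ORs are converted to per-DDD effects assuming linearity in
dose: the default is the through-origin least-squares slope of the two
category log-ORs against the class median doses (0.25, 0.75 DDD/day),

    slope = (0.25 * beta_low + 0.75 * beta_high) / (0.25**2 + 0.75**2),

with a high-category-only variant (beta_high / 0.75) as a sensitivity
option.  Multi-window combinations multiply per-DDD ORs (sum the log-ORs)
with full covariance propagation.  Fitted models can be projected into
event-free curves under static dosing regimens for a chosen covariate
profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import ipw_weights, missing_data
from .cox_wce import (
    FitResult,
    build_design,
    cox_report,
    fit_discrete_cox,
    fit_pooled_binary,
)
from .exposure_history import (
    CLASS_HIGH,
    CLASS_LOW,
    DOSE_CLASS_LABELS,
    HIGH_MEDIAN,
    LOW_MEDIAN,
    WINDOW_LAGS,
    WINDOW_NAMES,
    build_analysis_rows,
)
from .synthetic_cohort import apply_missingness, simulate_cohort

MSM_NUMERIC = [f"met_p_{c}_{w}" for w in WINDOW_NAMES for c in ("low", "high")]
MSM_CATEGORICAL = ["age_group", "ethnicity", "ses"]


@dataclass
class RegimenCurve:
    """Projected event-free proportion under a static dosing regimen."""

    regimen: str
    profile: dict
    quarters: np.ndarray       # follow-up quarters, 0 = index quarter
    event_free: np.ndarray     # starts at 1, nonincreasing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"quarter": self.quarters, "event_free": self.event_free,
             "regimen": self.regimen}
        )


def fit_msm(
    rows: pd.DataFrame,
    weights: pd.DataFrame | np.ndarray | None = None,
    numeric: list | None = None,
    categorical: list | None = None,
    cluster: bool = True,
) -> FitResult:
    """Weighted (or unweighted) pooled logistic MSM on at-risk rows.

    ``weights`` may be the frame from ``ipw_weights.compute_weights`` (its
    truncated weights are joined on subject and quarter) or an array aligned
    with ``rows``; ``None`` fits the unweighted MSM.  Confidence intervals
    use the cluster-robust covariance clustered on subject.
    """
    numeric = MSM_NUMERIC if numeric is None else list(numeric)
    categorical = MSM_CATEGORICAL if categorical is None else list(categorical)
    w = None
    if weights is not None:
        if isinstance(weights, pd.DataFrame):
            merged = rows[["subject_id", "quarter"]].merge(
                weights[["subject_id", "quarter", "weight_truncated"]],
                on=["subject_id", "quarter"],
                how="left",
            )
            if merged["weight_truncated"].isna().any():
                missing = merged.loc[merged["weight_truncated"].isna(),
                                     ["subject_id", "quarter"]]
                raise ValueError(
                    "weights missing for "
                    f"{len(missing)} analysis rows, e.g. {missing.head(5).to_dict('records')}"
                )
            w = merged["weight_truncated"].to_numpy(float)
        else:
            w = np.asarray(weights, dtype=float)
            if len(w) != len(rows):
                raise ValueError("weight array length does not match the analysis rows")
    X, names, meta = build_design(rows, numeric, categorical)
    return fit_pooled_binary(
        rows["event"].to_numpy(bool), X, names, rows["subject_id"].to_numpy(),
        link="logit", weights=w, cluster=cluster, meta=meta,
    )


def _per_ddd_contrast(fit: FitResult, window: str, medians: tuple, method: str) -> np.ndarray:
    lo_t, hi_t = f"met_p_low_{window}", f"met_p_high_{window}"
    c = np.zeros(len(fit.terms))
    m_low, m_high = medians
    if method == "slope":
        denom = m_low**2 + m_high**2
        c[fit.index(lo_t)] = m_low / denom
        c[fit.index(hi_t)] = m_high / denom
    elif method == "high":
        c[fit.index(hi_t)] = 1.0 / m_high
    else:
        raise ValueError(f"unknown per-DDD conversion method {method!r}")
    return c


def convert_or_per_ddd(
    fit: FitResult,
    window: str = "w1",
    medians: tuple = (LOW_MEDIAN, HIGH_MEDIAN),
    method: str = "slope",
    level: float = 0.95,
    robust: bool = True,
) -> dict:
    """Per-DDD odds ratio for one window from the two category log-ORs.

    ``method="slope"`` (default) regresses both category log-ORs through
    the origin against their median doses; ``method="high"`` rescales the
    high-dose log-OR alone.  The variance comes from the delta method on
    the fitted covariance.
    """
    c = _per_ddd_contrast(fit, window, medians, method)
    cov = fit.cov_robust if robust else fit.cov
    log_or = float(c @ fit.params)
    se = float(np.sqrt(c @ cov @ c))
    z = norm.ppf(0.5 + level / 2)
    return {
        "window": window,
        "log_estimate": log_or,
        "se": se,
        "estimate": float(np.exp(log_or)),
        "ci_low": float(np.exp(log_or - z * se)),
        "ci_high": float(np.exp(log_or + z * se)),
    }


def combine_msm_windows(
    fit: FitResult,
    windows: tuple = ("w2", "w3"),
    medians: tuple = (LOW_MEDIAN, HIGH_MEDIAN),
    method: str = "slope",
    level: float = 0.95,
    robust: bool = True,
) -> dict:
    """Combined per-DDD OR over several windows (product of per-window ORs),
    with the covariance of all four underlying category coefficients."""
    c = np.zeros(len(fit.terms))
    for w in windows:
        c += _per_ddd_contrast(fit, w, medians, method)
    cov = fit.cov_robust if robust else fit.cov
    log_or = float(c @ fit.params)
    se = float(np.sqrt(c @ cov @ c))
    z = norm.ppf(0.5 + level / 2)
    return {
        "windows": tuple(windows),
        "log_estimate": log_or,
        "se": se,
        "estimate": float(np.exp(log_or)),
        "ci_low": float(np.exp(log_or - z * se)),
        "ci_high": float(np.exp(log_or + z * se)),
    }


def msm_report(fit: FitResult, method: str = "slope", robust: bool = True) -> pd.DataFrame:
    """Per-DDD OR per window plus the 2-7-year combination (table-shaped)."""
    rows = []
    label = {"w1": "previous year", "w2": "years 2-4 before", "w3": "years 5-7 before"}
    for w in WINDOW_NAMES:
        r = convert_or_per_ddd(fit, w, method=method, robust=robust)
        rows.append({"period": label[w], "estimate": r["estimate"],
                     "ci_low": r["ci_low"], "ci_high": r["ci_high"]})
    comb = combine_msm_windows(fit, method=method, robust=robust)
    rows.append({"period": "years 2-7 before", "estimate": comb["estimate"],
                 "ci_low": comb["ci_low"], "ci_high": comb["ci_high"]})
    return pd.DataFrame(rows)


def _regimen_proportions(t: int, index_quarter: int, window: str) -> float:
    """Fraction of a window's quarters on-regimen when dosing is constant
    from the index quarter onward (the window fills up as time passes)."""
    a, b = WINDOW_LAGS[window]
    lo = max(t - b, index_quarter)
    hi = t - a
    return max(0, hi - lo + 1) / (b - a + 1)


def project_regimen_curve(
    fit: FitResult,
    regimen: str,
    profile: dict,
    horizon: int = 32,
    index_quarter: int = 8,
) -> RegimenCurve:
    """Event-free curve under a static dose regimen for a covariate profile.

    ``regimen`` is ``"none"``, ``"low"`` or ``"high"`` (held constant from
    the index quarter onward; no exposure before it).  ``profile`` maps the
    fitted categorical covariates to levels, e.g. ``{"age_group": "70-74",
    "ses": "high", "ethnicity": "ashkenazi"}``.  The curve multiplies
    (1 - hazard) over follow-up quarters, starting at 1.
    """
    if regimen not in DOSE_CLASS_LABELS:
        raise KeyError(f"unknown regimen {regimen!r}; expected one of {DOSE_CLASS_LABELS}")
    cls = DOSE_CLASS_LABELS.index(regimen)
    levels = fit.meta.get("categorical_levels", {})
    for col, val in profile.items():
        if col not in levels:
            raise KeyError(f"profile covariate {col!r} not in the fitted model")
        if val not in levels[col]:
            raise KeyError(f"level {val!r} of {col!r} not seen at fit time; "
                           f"known levels: {levels[col]}")

    qbins = fit.meta.get("quarter_bins") or {}
    bin_levels = levels.get("quarter", [])
    surv = [1.0]
    quarters = np.arange(horizon + 1)
    for step in range(horizon):
        t = index_quarter + step
        x = np.zeros(len(fit.terms))
        x[fit.terms.index("intercept")] = 1.0
        if bin_levels:
            known = [q for q in qbins if q <= t]
            b = qbins[max(known)] if known else bin_levels[0]
            name = f"quarter[{b}]"
            if name in fit.terms:  # reference bin has no column
                x[fit.terms.index(name)] = 1.0
        for col, val in profile.items():
            name = f"{col}[{val}]"
            if name in fit.terms:
                x[fit.terms.index(name)] = 1.0
        if cls in (CLASS_LOW, CLASS_HIGH):
            tag = "low" if cls == CLASS_LOW else "high"
            for w in WINDOW_NAMES:
                term = f"met_p_{tag}_{w}"
                if term in fit.terms:
                    x[fit.terms.index(term)] = _regimen_proportions(t, index_quarter, w)
        hazard = float(expit(x @ fit.params))
        surv.append(surv[-1] * (1.0 - hazard))
    return RegimenCurve(
        regimen=regimen, profile=dict(profile), quarters=quarters,
        event_free=np.asarray(surv),
    )


def run_msm_analysis(
    panel: pd.DataFrame,
    strategy: str = "indicator",
    weighted: bool = True,
    m: int = 5,
    seed: int = 0,
    bounds: tuple = ipw_weights.DEFAULT_BOUNDS,
    cluster: bool = True,
) -> dict:
    """Missing-data handling + weight estimation + MSM fit, end to end.

    ``strategy`` is ``"indicator"``, ``"locf"``, ``"mi"`` or ``"none"``
    (complete data required).  For ``"mi"`` the ``m`` per-imputation fits
    are pooled with Rubin's rules.  Returns the fit plus weight diagnostics.
    """
    if strategy == "locf":
        panels = [missing_data.apply_locf(panel)]
    elif strategy == "mi":
        if m < 2:
            raise ValueError("multiple imputation needs m >= 2")
        panels = missing_data.sequential_impute(panel, m=m, seed=seed)
    elif strategy in ("indicator", "none"):
        panels = [panel]
    else:
        raise ValueError(f"unknown missing-data strategy {strategy!r}")

    fits, diagnostics = [], None
    for p in panels:
        covs = ipw_weights.build_weight_covariates(p)
        if strategy == "indicator":
            covs = missing_data.apply_missing_indicator(covs)
        rows = build_analysis_rows(p)
        if weighted:
            den = ipw_weights.fit_weight_model(covs)
            num = ipw_weights.fit_numerator_model(covs)
            wts = ipw_weights.compute_weights(covs, den, num, bounds=bounds)
            diagnostics = ipw_weights.weight_diagnostics(wts)
            fits.append(fit_msm(rows, weights=wts, cluster=cluster))
        else:
            fits.append(fit_msm(rows, cluster=cluster))
    fit = fits[0] if len(fits) == 1 else missing_data.pool_rubin(fits)
    return {
        "fit": fit,
        "weight_diagnostics": diagnostics,
        "strategy": strategy,
        "weighted": weighted,
        "n_subjects": int(panels[0]["subject_id"].nunique()),
    }


def run_full_pipeline(config) -> dict:
    """Simulate (or load) a cohort and produce every headline output.

    ``config`` is a ``cli_report.RunConfig`` (or anything with the same
    attributes).  Returns the windowed-Cox HR table, unweighted and weighted
    MSM per-DDD OR tables, weight diagnostics and the projected regimen
    curves; the whole bundle is a deterministic function of the seed.
    """
    from .synthetic_cohort import read_panel_csv  # light import cycle guard

    if getattr(config, "panel_csv", None):
        panel = read_panel_csv(config.panel_csv)
    else:
        dgp = config.dgp
        panel = simulate_cohort(dgp)
        if dgp.missing_rate_hba1c > 0 or dgp.missing_rate_glucose > 0:
            panel = apply_missingness(panel, dgp)

    strategy = config.strategy
    results = {"seed": config.seed, "strategy": strategy}

    # the Cox analysis uses complete exposure histories only, so missing
    # biomarkers do not affect it
    rows = build_analysis_rows(panel)
    cox_fit = fit_discrete_cox(rows)
    results["cox"] = {"fit": cox_fit, "table": cox_report(cox_fit)}

    unweighted = run_msm_analysis(panel, strategy=strategy, weighted=False,
                                  m=config.m, seed=config.seed, bounds=config.weight_bounds)
    weighted = run_msm_analysis(panel, strategy=strategy, weighted=True,
                                m=config.m, seed=config.seed, bounds=config.weight_bounds)
    results["msm_unweighted"] = {"fit": unweighted["fit"],
                                 "table": msm_report(unweighted["fit"])}
    results["msm_weighted"] = {"fit": weighted["fit"],
                               "table": msm_report(weighted["fit"])}
    results["weight_diagnostics"] = weighted["weight_diagnostics"]

    profile = dict(config.profile)
    curves = {}
    for regimen in config.regimens:
        curve = project_regimen_curve(weighted["fit"], regimen, profile,
                                      horizon=config.horizon,
                                      index_quarter=int(panel[panel["at_risk"]]["quarter"].min()))
        curves[regimen] = curve
    results["curves"] = curves
    return results
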