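"""Inverse-probability-of-treatment weights for a 3-class quarterly dose.

Each quarter's metformin dose class (none / low / high) is modelled with
polytomous (multinomial) logistic regression.  The denominator model
conditions on treatment history and the time-varying glucose-control
confounders; the numerator (stabilizing) model conditions on treatment
history and time-invariant covariates only.  The stabilized weight at
quarter ``q`` is the product over quarters 0..q of the per-quarter ratios
numerator-probability / denominator-probability of the class actually
received; cumulation starts at diagnosis (quarter 0) even though only
at-risk quarters enter the outcome model.  The cumulative stabilized
weight is truncated at [0.1, 10.0] by default.

Treatment history is encoded as the previous quarter's dose class plus the
cumulative proportions of prior quarters spent in the low and high classes
(recency and duration in four numbers).  The confounders are the baseline
HbA1c and glucose values and their averages over the previous (up to)
3 quarters, using whatever values are non-missing after the chosen
missing-data handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cox_wce import FitError
from .exposure_history import CLASS_HIGH, CLASS_LOW, DOSE_CLASS_LABELS, classify_dose

DEFAULT_BOUNDS = (0.1, 10.0)
POSITIVITY_FLOOR = 1e-6

#: biomarker covariates of the weighting model (may carry missing values)
BIOMARKER_COVARIATES = ("hba1c0", "glucose0", "hba1c_avg3", "glucose_avg3")

HISTORY_COVARIATES = ("quarter", "prev_low", "prev_high", "cum_p_low", "cum_p_high")
BASELINE_CATEGORICAL = ("age_group", "ethnicity", "ses")


class PositivityWarning(UserWarning):
    """Estimated probability of the received class is essentially zero."""


def _lagged_mean(values: np.ndarray, baseline: np.ndarray, k: int = 3) -> np.ndarray:
    """Per-row mean of the previous up-to-``k`` entries (NaN-aware).

    ``values`` is (n_subjects, n_quarters); column ``q`` of the result is
    the mean of the observed values among columns ``q-k..q-1``; at ``q = 0``
    the baseline value stands in; all-missing look-backs give NaN.
    """
    n, nq = values.shape
    filled = np.nan_to_num(values, nan=0.0)
    obs = (~np.isnan(values)).astype(float)
    pf = np.zeros((n, nq + 1))
    po = np.zeros((n, nq + 1))
    np.cumsum(filled, axis=1, out=pf[:, 1:])
    np.cumsum(obs, axis=1, out=po[:, 1:])
    t = np.arange(nq)
    lo = np.clip(t - k, 0, nq)
    s = pf[:, t] - pf[:, lo]
    c = po[:, t] - po[:, lo]
    with np.errstate(invalid="ignore"):
        out = s / c
    out[:, 0] = baseline
    return out


def build_weight_covariates(panel: pd.DataFrame) -> pd.DataFrame:
    """Per subject-quarter covariates of the treatment models.

    Includes all quarters from diagnosis onward (not only at-risk rows).
    Biomarker covariates may be NaN wherever the panel had missing values;
    apply a missing-data strategy before fitting.
    """
    panel = panel.sort_values(["subject_id", "quarter"], kind="stable")
    subjects = panel["subject_id"].unique()
    sub_idx = pd.Series(np.arange(len(subjects)), index=subjects)
    nq = int(panel["quarter"].max()) + 1
    si = sub_idx[panel["subject_id"]].to_numpy()
    qi = panel["quarter"].to_numpy(int)

    def wide(col, fill=np.nan):
        m = np.full((len(subjects), nq), fill)
        m[si, qi] = panel[col].to_numpy(float)
        return m

    cls = classify_dose(np.nan_to_num(panel["metformin_ddd"].to_numpy(float)))
    cls_w = np.zeros((len(subjects), nq), dtype=float)
    cls_w[si, qi] = cls

    # previous-quarter class and cumulative class proportions (prior quarters)
    prev = np.zeros_like(cls_w)
    prev[:, 1:] = cls_w[:, :-1]
    cum_low = np.zeros((len(subjects), nq))
    cum_high = np.zeros((len(subjects), nq))
    low_prefix = np.cumsum(cls_w == CLASS_LOW, axis=1)
    high_prefix = np.cumsum(cls_w == CLASS_HIGH, axis=1)
    q_idx = np.arange(1, nq)
    cum_low[:, 1:] = low_prefix[:, :-1] / q_idx
    cum_high[:, 1:] = high_prefix[:, :-1] / q_idx

    base_h = panel.groupby("subject_id", sort=False)["hba1c0"].first().reindex(subjects)
    base_g = panel.groupby("subject_id", sort=False)["glucose0"].first().reindex(subjects)
    h_avg3 = _lagged_mean(wide("hba1c"), base_h.to_numpy())
    g_avg3 = _lagged_mean(wide("glucose"), base_g.to_numpy())

    covs = pd.DataFrame(
        {
            "subject_id": panel["subject_id"].to_numpy(),
            "quarter": qi.astype(float),
            "dose_class": cls,
            "prev_low": (prev[si, qi] == CLASS_LOW).astype(float),
            "prev_high": (prev[si, qi] == CLASS_HIGH).astype(float),
            "cum_p_low": cum_low[si, qi],
            "cum_p_high": cum_high[si, qi],
            "hba1c0": panel["hba1c0"].to_numpy(float),
            "glucose0": panel["glucose0"].to_numpy(float),
            "hba1c_avg3": h_avg3[si, qi],
            "glucose_avg3": g_avg3[si, qi],
            "age_group": panel["age_group"].to_numpy(),
            "ethnicity": panel["ethnicity"].to_numpy(),
            "ses": panel["ses"].to_numpy(),
        }
    )
    return covs.reset_index(drop=True)


@dataclass
class DoseClassModel:
    """Fitted polytomous logistic model for the quarterly dose class."""

    result: object
    columns: list          # design columns after the intercept
    cat_levels: dict       # categorical level lists (reference = first)
    classes: tuple = (0, 1, 2)

    @property
    def converged(self) -> bool:
        return bool(self.result.mle_retvals.get("converged", True))

    def design(self, covs: pd.DataFrame) -> np.ndarray:
        n = len(covs)
        blocks = [np.ones((n, 1))]
        for col in self.columns:
            if col in self.cat_levels:
                for lv in self.cat_levels[col][1:]:
                    blocks.append((covs[col].to_numpy() == lv).astype(float).reshape(-1, 1))
            else:
                blocks.append(covs[col].to_numpy(float).reshape(-1, 1))
        return np.hstack(blocks)

    def predict_proba(self, covs: pd.DataFrame) -> np.ndarray:
        """(n, 3) class probabilities; rows sum to 1."""
        return np.asarray(self.result.predict(self.design(covs)))


def _fit_multinomial(covs: pd.DataFrame, columns: list, cat_columns: list) -> DoseClassModel:
    present = np.unique(covs["dose_class"].to_numpy(int))
    for k in (0, 1, 2):
        if k not in present:
            raise FitError(
                f"dose class {DOSE_CLASS_LABELS[k]!r} absent from the data; "
                "the 3-class treatment model is not identifiable"
            )
    cat_levels = {c: sorted(pd.unique(covs[c]).tolist()) for c in cat_columns}
    model = DoseClassModel(result=None, columns=list(columns), cat_levels=cat_levels)
    X = model.design(covs)
    if np.isnan(X).any():
        bad = [c for c in columns if c not in cat_levels and covs[c].isna().any()]
        raise FitError(
            f"weighting covariates contain missing values ({bad}); "
            "apply a missing-data strategy first"
        )
    y = covs["dose_class"].to_numpy(int)
    mn = sm.MNLogit(y, X)
    res = mn.fit(method="newton", maxiter=200, disp=0,
                 start_params=np.zeros(2 * X.shape[1]))
    if not res.mle_retvals.get("converged", False):
        raise FitError(f"polytomous dose-class model did not converge: {res.mle_retvals}")
    model.result = res
    return model


def fit_weight_model(
    covs: pd.DataFrame,
    confounders: tuple = BIOMARKER_COVARIATES,
    extra: tuple = (),
) -> DoseClassModel:
    """Denominator model: treatment history + time-varying confounders.

    ``covs`` comes from :func:`build_weight_covariates` (after missing-data
    handling).  ``extra`` appends additional columns, e.g. missingness
    indicators.  Pass ``confounders=()`` and strip the history columns for
    an intercept-only model.
    """
    if "dose_class" not in covs.columns:  # accept a raw panel for convenience
        covs = build_weight_covariates(covs)
    # constant indicator columns (nothing was missing) would be collinear
    # with the intercept, so only informative ones enter the model
    indicator_cols = [c for c in covs.columns
                      if c.endswith("_missing") and covs[c].nunique() > 1]
    columns = list(HISTORY_COVARIATES) + list(BASELINE_CATEGORICAL)
    columns += list(confounders) + list(extra) + indicator_cols
    cat = [c for c in columns if c in BASELINE_CATEGORICAL]
    return _fit_multinomial(covs, columns, cat)


def fit_numerator_model(covs: pd.DataFrame) -> DoseClassModel:
    """Stabilizing model: treatment history + time-invariant covariates only."""
    if "dose_class" not in covs.columns:
        covs = build_weight_covariates(covs)
    columns = list(HISTORY_COVARIATES) + list(BASELINE_CATEGORICAL)
    return _fit_multinomial(covs, columns, list(BASELINE_CATEGORICAL))


def fit_intercept_only_model(covs: pd.DataFrame) -> DoseClassModel:
    """Marginal class-frequency model (diagnostic baseline)."""
    return _fit_multinomial(covs, [], [])


def compute_weights(
    covs: pd.DataFrame,
    denominator: DoseClassModel,
    numerator: DoseClassModel,
    bounds: tuple = DEFAULT_BOUNDS,
    positivity_floor: float = POSITIVITY_FLOOR,
) -> pd.DataFrame:
    """Stabilized, truncated IPW per subject-quarter.

    Returns a frame keyed by (subject_id, quarter) with the denominator and
    numerator probabilities of the received class, the per-quarter ratio,
    the cumulative stabilized weight (product of ratios from quarter 0
    through the current quarter) and its truncation to ``bounds``.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"truncation bounds must satisfy lower < upper, got {bounds}")
    covs = covs.sort_values(["subject_id", "quarter"], kind="stable").reset_index(drop=True)
    received = covs["dose_class"].to_numpy(int)
    n = len(covs)
    p_den = denominator.predict_proba(covs)[np.arange(n), received]
    p_num = numerator.predict_proba(covs)[np.arange(n), received]

    low_p = p_den < positivity_floor
    if low_p.any():
        offenders = covs.loc[low_p, ["subject_id", "quarter"]].to_records(index=False)
        warnings.warn(
            f"positivity: {low_p.sum()} subject-quarters with denominator probability "
            f"< {positivity_floor:g}: {list(offenders)[:10]}",
            PositivityWarning,
            stacklevel=2,
        )

    ratio = p_num / p_den
    weight = (
        pd.Series(ratio).groupby(covs["subject_id"].to_numpy(), sort=False).cumprod().to_numpy()
    )
    out = pd.DataFrame(
        {
            "subject_id": covs["subject_id"],
            "quarter": covs["quarter"].astype(int),
            "p_denominator": p_den,
            "p_numerator": p_num,
            "ratio": ratio,
            "weight": weight,
            "weight_truncated": np.clip(weight, lo, hi),
        }
    )
    out.attrs["bounds"] = (float(lo), float(hi))
    return out


def truncate_weights(weights: np.ndarray, bounds: tuple = DEFAULT_BOUNDS) -> np.ndarray:
    """Clip weights to the truncation bounds (idempotent, monotone)."""
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"truncation bounds must satisfy lower < upper, got {bounds}")
    return np.clip(np.asarray(weights, dtype=float), lo, hi)


def weight_diagnostics(weights: pd.DataFrame) -> dict:
    """Summary of the stabilized weights before truncation.

    Reports the mean, selected percentiles, extremes, and the fraction of
    subject-quarters (and of subjects) whose cumulative weight required
    truncation.
    """
    if len(weights) == 0:
        raise ValueError("empty weight series")
    w = weights["weight"].to_numpy(float)
    lo, hi = weights.attrs.get("bounds", DEFAULT_BOUNDS)
    truncated = (w < lo) | (w > hi)
    by_subject = pd.Series(truncated).groupby(weights["subject_id"].to_numpy()).any()
    pct = np.percentile(w, [1, 25, 50, 75, 99])
    return {
        "mean": float(w.mean()),
        "min": float(w.min()),
        "p1": float(pct[0]),
        "p25": float(pct[1]),
        "median": float(pct[2]),
        "p75": float(pct[3]),
        "p99": float(pct[4]),
        "max": float(w.max()),
        "frac_truncated_rows": float(truncated.mean()),
        "frac_truncated_subjects": float(by_subject.mean()),
        "n_rows": int(len(w)),
        "n_subjects": int(len(by_subject)),
    }
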