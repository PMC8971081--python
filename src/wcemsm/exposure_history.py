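"""Dose-history covariates for discrete-time pharmacoepidemiology.

Follow-up is cut into quarter-years indexed from diabetes diagnosis
(quarter 0).  Drug exposure enters the outcome models through three fixed
look-back windows relative to the current quarter ``t``:

* ``w1`` -- the previous year, lags 1-4;
* ``w2`` -- the second to fourth years before, lags 5-16;
* ``w3`` -- the fifth to seventh years before, lags 17-28.

The current quarter itself is excluded from every window, so covariates at
``t`` depend only on strictly past exposure (no same-quarter reverse
causation by construction).  Quarters before diagnosis contribute zero dose
and class ``NONE``, and the full nominal window length is always used as
the denominator, so the covariates are continuous in ``t``.

Two covariate families are produced per window: the average dose in
DDD/day (continuous, used by the discrete-time Cox model) and the
proportions of window quarters spent in the low / high dose class (used by
the marginal structural model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: average number of days in a quarter-year, used to convert a quarter's
#: total purchased DDD into an average DDD/day
DAYS_PER_QUARTER = 91.25

# dose classes: 0 DDD/day -> NONE, (0, 0.5) -> LOW, [0.5, inf) -> HIGH
CLASS_NONE, CLASS_LOW, CLASS_HIGH = 0, 1, 2
DOSE_CLASS_LABELS = ("none", "low", "high")
HIGH_THRESHOLD = 0.5
#: representative median doses of the nonzero classes (DDD/day)
LOW_MEDIAN, HIGH_MEDIAN = 0.25, 0.75
CLASS_MEDIANS = np.array([0.0, LOW_MEDIAN, HIGH_MEDIAN])

#: look-back windows as inclusive lag ranges relative to the current quarter
WINDOW_LAGS = {"w1": (1, 4), "w2": (5, 16), "w3": (17, 28)}
WINDOW_NAMES = tuple(WINDOW_LAGS)

#: non-metformin glucose-lowering medication groups (by mechanism of action):
#: insulins; secretagogues + incretin mimetics; alpha-glucosidase inhibitors;
#: thiazolidinediones
OTHER_GLM_GROUPS = ("insulin", "secretagogue", "agi", "tzd")

#: required columns of a person-quarter panel (the data dictionary)
PANEL_COLUMNS = (
    "subject_id",
    "quarter",
    "age_group",
    "ethnicity",
    "ses",
    "hba1c0",
    "glucose0",
    "hba1c",
    "glucose",
    "metformin_ddd",
    "insulin_ddd",
    "secretagogue_ddd",
    "agi_ddd",
    "tzd_ddd",
    "at_risk",
    "event",
    "censored",
)


class DataError(ValueError):
    """Raised when input tables violate the person-quarter contract."""


@dataclass(frozen=True)
class ExposureWindows:
    """Window summaries of one subject's dose history at one quarter."""

    w1_avg: float
    w2_avg: float
    w3_avg: float
    p_low_w1: float
    p_high_w1: float
    p_low_w2: float
    p_high_w2: float
    p_low_w3: float
    p_high_w3: float


def classify_dose(ddd):
    """Map a nonnegative DDD/day dose to its class (0=none, 1=low, 2=high).

    Boundaries are exact: 0 -> NONE, 0 < d < 0.5 -> LOW, d >= 0.5 -> HIGH.
    Accepts a scalar or array; negative input raises :class:`DataError`.
    """
    arr = np.asarray(ddd, dtype=float)
    if np.any(arr < 0):
        raise DataError("dose must be nonnegative (DDD/day)")
    cls = np.where(arr >= HIGH_THRESHOLD, CLASS_HIGH, np.where(arr > 0, CLASS_LOW, CLASS_NONE))
    if np.isscalar(ddd) or arr.ndim == 0:
        return int(cls)
    return cls.astype(np.int64)


def quarterize_purchases(purchases: pd.DataFrame, n_quarters: int) -> np.ndarray:
    """Convert one subject's purchase records into a per-quarter DDD/day series.

    ``purchases`` needs columns ``quarter`` (0-based index since diagnosis)
    and ``ddd`` (total DDD bought in that quarter).  The quarter's dose is
    the total DDD purchased divided by ``DAYS_PER_QUARTER`` (amount purchased
    is assumed consumed); quarters with no purchase are 0.
    """
    series = np.zeros(int(n_quarters))
    if len(purchases) == 0:
        return series
    q = np.asarray(purchases["quarter"], dtype=int)
    amt = np.asarray(purchases["ddd"], dtype=float)
    if np.any(amt < 0):
        raise DataError("purchase quantities must be nonnegative DDD")
    if np.any((q < 0) | (q >= n_quarters)):
        raise DataError("purchase quarter index out of range")
    np.add.at(series, q, amt)
    return series / DAYS_PER_QUARTER


def _window_sums(values: np.ndarray) -> dict:
    """Sliding window sums over the three lag windows.

    ``values`` is an (n_subjects, n_quarters) matrix; returns, per window,
    an (n_subjects, n_quarters) matrix whose column ``t`` is the sum of
    ``values`` over quarters ``[t-b, t-a]`` (clipped at quarter 0, i.e.
    pre-diagnosis quarters contribute 0).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, q = values.shape
    prefix = np.zeros((n, q + 1))
    np.cumsum(values, axis=1, out=prefix[:, 1:])
    t = np.arange(q)
    out = {}
    for name, (a, b) in WINDOW_LAGS.items():
        hi = np.clip(t - a + 1, 0, q)
        lo = np.clip(t - b, 0, q)
        out[name] = prefix[:, hi] - prefix[:, lo]
    return out


def window_means(values: np.ndarray) -> dict:
    """Window averages (full nominal window length as denominator)."""
    sums = _window_sums(values)
    return {w: sums[w] / (b - a + 1) for w, (a, b) in WINDOW_LAGS.items()}


def compute_windows(dose_series, t: int, index_quarter: int = 0) -> ExposureWindows:
    """Exposure-window summaries for a single dose series at quarter ``t``.

    The series is indexed from quarter 0 (diagnosis); ``t`` must be at or
    after the index quarter (first at-risk quarter).
    """
    if t < index_quarter:
        raise DataError(f"current quarter {t} precedes index quarter {index_quarter}")
    series = np.asarray(dose_series, dtype=float)
    if t >= series.size:
        # windows only look backwards, so pad on the right if needed
        series = np.concatenate([series, np.zeros(t + 1 - series.size)])
    cls = classify_dose(series)
    avg = window_means(series[None, :])
    p_low = window_means((cls == CLASS_LOW).astype(float)[None, :])
    p_high = window_means((cls == CLASS_HIGH).astype(float)[None, :])
    return ExposureWindows(
        w1_avg=float(avg["w1"][0, t]),
        w2_avg=float(avg["w2"][0, t]),
        w3_avg=float(avg["w3"][0, t]),
        p_low_w1=float(p_low["w1"][0, t]),
        p_high_w1=float(p_high["w1"][0, t]),
        p_low_w2=float(p_low["w2"][0, t]),
        p_high_w2=float(p_high["w2"][0, t]),
        p_low_w3=float(p_low["w3"][0, t]),
        p_high_w3=float(p_high["w3"][0, t]),
    )


def panel_violations(panel: pd.DataFrame) -> pd.DataFrame:
    """Check person-quarter invariants; one row per violation.

    Rules checked (column ``rule`` of the result):

    * ``negative_dose`` -- any dose column below 0
    * ``quarters_not_contiguous`` -- quarters not 0..k without gaps
    * ``multiple_events`` -- more than one event row for a subject
    * ``rows_after_terminal`` -- records after an event or censoring quarter
    * ``event_not_at_risk`` -- an event in a quarter not flagged at risk
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise DataError(f"panel is missing required columns: {missing}")
    rows = []

    dose_cols = ["metformin_ddd"] + [f"{g}_ddd" for g in OTHER_GLM_GROUPS]
    for col in dose_cols:
        bad = panel.loc[panel[col] < 0, ["subject_id", "quarter"]]
        for sid, q in bad.itertuples(index=False):
            rows.append((sid, q, "negative_dose"))

    for sid, grp in panel.groupby("subject_id", sort=False):
        q = np.sort(np.asarray(grp["quarter"], dtype=int))
        if not np.array_equal(q, np.arange(len(q))):
            rows.append((sid, int(q[0]), "quarters_not_contiguous"))
            continue
        grp = grp.sort_values("quarter")
        ev = np.asarray(grp["event"], dtype=bool)
        cs = np.asarray(grp["censored"], dtype=bool)
        ar = np.asarray(grp["at_risk"], dtype=bool)
        if ev.sum() > 1:
            rows.append((sid, int(grp["quarter"].iloc[int(np.argmax(ev))]), "multiple_events"))
        term = ev | cs
        if term.any():
            first = int(np.argmax(term))
            if first < len(grp) - 1:
                rows.append((sid, int(grp["quarter"].iloc[first + 1]), "rows_after_terminal"))
        if np.any(ev & ~ar):
            q_bad = int(grp["quarter"].iloc[int(np.argmax(ev & ~ar))])
            rows.append((sid, q_bad, "event_not_at_risk"))

    return pd.DataFrame(rows, columns=["subject_id", "quarter", "rule"])


def _require_valid(panel: pd.DataFrame) -> None:
    viol = panel_violations(panel)
    if len(viol):
        offenders = sorted(viol["subject_id"].unique().tolist())
        raise DataError(
            f"panel violates person-quarter invariants for subjects {offenders[:20]}"
            + ("..." if len(offenders) > 20 else "")
            + f" ({len(viol)} violations; rules: {sorted(viol['rule'].unique())})"
        )


def build_analysis_rows(panel: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Person-period table for the outcome models.

    One row per at-risk subject-quarter (from the index quarter until the
    event/censoring quarter inclusive), carrying for metformin the three
    window averages and the six window dose-class proportions, the three
    window averages for each other-GLM group, baseline covariates, the
    quarter index and the event indicator.  Subjects whose history ends
    before their first at-risk quarter contribute no rows.
    """
    if validate:
        _require_valid(panel)
    panel = panel.sort_values(["subject_id", "quarter"], kind="stable")
    subjects = panel["subject_id"].unique()
    sub_idx = pd.Series(np.arange(len(subjects)), index=subjects)
    n_quarters = int(panel["quarter"].max()) + 1

    def wide(col):
        m = np.zeros((len(subjects), n_quarters))
        m[sub_idx[panel["subject_id"]].to_numpy(), panel["quarter"].to_numpy(int)] = (
            panel[col].to_numpy(float)
        )
        return m

    met = wide("metformin_ddd")
    avg = window_means(met)
    p_low = window_means(((met > 0) & (met < HIGH_THRESHOLD)).astype(float))
    p_high = window_means((met >= HIGH_THRESHOLD).astype(float))
    other_avg = {g: window_means(wide(f"{g}_ddd")) for g in OTHER_GLM_GROUPS}

    at_risk = panel[panel["at_risk"].astype(bool)]
    si = sub_idx[at_risk["subject_id"]].to_numpy()
    qi = at_risk["quarter"].to_numpy(int)

    out = {
        "subject_id": at_risk["subject_id"].to_numpy(),
        "quarter": qi,
        "event": at_risk["event"].astype(bool).to_numpy(),
    }
    for c in ("age_group", "ethnicity", "ses", "hba1c0", "glucose0"):
        out[c] = at_risk[c].to_numpy()
    for w in WINDOW_NAMES:
        out[f"met_{w}_avg"] = avg[w][si, qi]
        out[f"met_p_low_{w}"] = p_low[w][si, qi]
        out[f"met_p_high_{w}"] = p_high[w][si, qi]
    for g in OTHER_GLM_GROUPS:
        for w in WINDOW_NAMES:
            out[f"{g}_{w}_avg"] = other_avg[g][w][si, qi]
    return pd.DataFrame(out).reset_index(drop=True)
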