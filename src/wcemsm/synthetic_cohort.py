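"""Synthetic person-quarter cohorts with treatment-confounder feedback.

The generator emulates the data structure of a claims-based incident-diabetes
cohort followed for prostate cancer: quarterly metformin dose histories in
DDD/day, four other glucose-lowering medication (GLM) groups, glycaemic
markers (HbA1c in %, blood glucose in mg/dL) with per-quarter missingness,
and a discrete-time cancer hazard.  Its causal structure is exactly the one
the analysis pipeline assumes:

* biomarkers follow Gaussian AR(1) processes whose level is shifted by the
  current metformin dose (treatment -> confounder);
* each quarter's dose class (none / low / high) is drawn from a 3-category
  logit model given the previous class and the mean HbA1c over the previous
  3 quarters (confounder -> treatment), with dose set to the class median
  (0 / 0.25 / 0.75 DDD/day);
* the event hazard is a logit model in the three look-back window averages
  of dose (computed exactly as :mod:`wcemsm.exposure_history` defines them),
  recent glycaemia, and baseline covariates (treatment, confounder ->
  outcome).

Because the hazard uses a logit link with window covariates, the generator
is in the model family fitted downstream, so parameter-recovery tests are
free of link misspecification.  All ground-truth coefficients live in
:class:`DgpConfig` for recovery tests.  Default magnitudes are illustrative,
not calibrated to any real prescribing data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .exposure_history import (
    CLASS_MEDIANS,
    OTHER_GLM_GROUPS,
    PANEL_COLUMNS,
    WINDOW_LAGS,
)

AGE_GROUPS = (
    "<45", "45-49", "50-54", "55-59", "60-64",
    "65-69", "70-74", "75-79", "80-84", "85-89",
)
ETHNICITY_GROUPS = ("ashkenazi", "sephardic", "israeli-born", "arab", "yemenite-ethiopian")
SES_GROUPS = ("low", "medium", "high", "missing")


class ConfigError(ValueError):
    """Raised when a DGP configuration field is invalid; names the field."""


@dataclass
class DoseModelParams:
    """3-category logit for the quarterly dose class (reference: none).

    Utilities for the low/high classes are linear in the mean HbA1c over the
    previous 3 quarters (centred at ``hba1c_ref``), dummies for the previous
    quarter's class, and a linear quarter trend.
    """

    intercept_low: float = -2.0
    intercept_high: float = -3.5
    hba1c_coef_low: float = 0.4    # per % HbA1c above reference
    hba1c_coef_high: float = 0.6
    hba1c_ref: float = 7.0
    prev_low_on_low: float = 2.5   # persistence / escalation effects
    prev_low_on_high: float = 1.2
    prev_high_on_low: float = 1.2
    prev_high_on_high: float = 3.5
    quarter_trend: float = 0.02    # per quarter, both utilities


@dataclass
class HazardParams:
    """Quarterly event hazard on the logit scale.

    ``beta_w1/w2/w3`` are per-DDD log-odds ratios applied to the window
    average doses; biomarker effects are per unit above the reference
    (negative by default: better glycaemia control is associated with higher
    prostate-cancer risk in this literature, i.e. raw glucose/HbA1c carry
    negative log-ORs).  Defaults mimic the magnitudes of the motivating
    analysis (HR ~1.5 for the previous year, ~0.6 for years 2-4).
    """

    base_logit: float = -5.3       # ~0.5% per quarter baseline
    beta_w1: float = float(np.log(1.5))
    beta_w2: float = float(np.log(0.62))
    beta_w3: float = float(np.log(0.94))
    hba1c_coef: float = -0.2       # per % HbA1c (mean over previous 3 quarters)
    glucose_coef: float = -0.003   # per mg/dL (mean over previous 3 quarters)
    hba1c_ref: float = 7.0
    glucose_ref: float = 150.0
    age_coef: float = 0.15         # per 5-year age group above the middle group
    age_ref_index: int = 4


@dataclass
class DgpConfig:
    """Ground-truth parameters of the synthetic cohort."""

    n_subjects: int = 2000
    n_quarters: int = 40
    index_quarter: int = 8         # follow-up starts 2 years after diagnosis
    baseline_age_probs: tuple = (0.08, 0.10, 0.13, 0.15, 0.15, 0.13, 0.10, 0.08, 0.05, 0.03)
    ethnicity_probs: tuple = (0.301, 0.282, 0.189, 0.173, 0.055)
    ses_probs: tuple = (0.426, 0.380, 0.166, 0.028)
    hba1c0_mean: float = 7.5       # %
    hba1c0_sd: float = 1.1
    glucose0_mean: float = 150.0   # mg/dL
    glucose0_sd: float = 35.0
    ar_coefficient: float = 0.85   # biomarker persistence
    hba1c_innovation_sd: float = 0.35
    glucose_innovation_sd: float = 12.0
    treatment_effect_on_hba1c: float = -1.0    # steady-state % shift per DDD/day
    treatment_effect_on_glucose: float = -30.0  # steady-state mg/dL shift per DDD/day
    dose_logit_params: DoseModelParams = field(default_factory=DoseModelParams)
    hazard_params: HazardParams = field(default_factory=HazardParams)
    other_glm_start_prob: float = 0.01  # per-quarter chance of starting each other-GLM group
    censor_hazard: float = 0.01    # per-quarter noninformative loss
    missing_rate_hba1c: float = 0.35
    missing_rate_glucose: float = 0.22
    missing_dose_shift: float = 0.0  # logit shift of missingness per dose class (MAR stress)
    exempt_baseline_from_missingness: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("baseline_age_probs", "ethnicity_probs", "ses_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ConfigError(f"{name} must be nonnegative and sum to 1")
        for name in ("missing_rate_hba1c", "missing_rate_glucose", "censor_hazard",
                     "other_glm_start_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.index_quarter < self.n_quarters:
            raise ConfigError("index_quarter must satisfy 0 <= index_quarter < n_quarters")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be positive")
        for name in ("hba1c0_sd", "glucose0_sd", "hba1c_innovation_sd", "glucose_innovation_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DgpConfig":
        d = dict(d)
        if isinstance(d.get("dose_logit_params"), dict):
            d["dose_logit_params"] = DoseModelParams(**d["dose_logit_params"])
        if isinstance(d.get("hazard_params"), dict):
            d["hazard_params"] = HazardParams(**d["hazard_params"])
        for name in ("baseline_age_probs", "ethnicity_probs", "ses_probs"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


def default_dgp_config(seed: int = 0) -> DgpConfig:
    """Default configuration; two calls return identical configs."""
    cfg = DgpConfig(seed=seed)
    cfg.validate()
    return cfg


def null_effect_config(seed: int = 0, **overrides) -> DgpConfig:
    """Config with a truly null total metformin effect but strong confounding.

    Window coefficients are zero and metformin does not move the biomarkers
    (so there is no mediated pathway either), while HbA1c still drives both
    prescribing and the hazard: the unweighted analysis is confounded, the
    correctly weighted one is not.
    """
    cfg = default_dgp_config(seed)
    cfg.hazard_params = dataclasses.replace(
        cfg.hazard_params, beta_w1=0.0, beta_w2=0.0, beta_w3=0.0, hba1c_coef=-0.3
    )
    cfg.treatment_effect_on_hba1c = 0.0
    cfg.treatment_effect_on_glucose = 0.0
    cfg.missing_rate_hba1c = 0.0
    cfg.missing_rate_glucose = 0.0
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def recovery_config(seed: int = 0, beta_w1: float = float(np.log(1.5)),
                    beta_w2: float = float(np.log(0.6)), beta_w3: float = 0.0,
                    **overrides) -> DgpConfig:
    """Config for parameter-recovery tests: known window effects, no
    biomarker pathway into the hazard (so the window fit is unconfounded)."""
    cfg = default_dgp_config(seed)
    cfg.hazard_params = dataclasses.replace(
        cfg.hazard_params, beta_w1=beta_w1, beta_w2=beta_w2, beta_w3=beta_w3,
        hba1c_coef=0.0, glucose_coef=0.0,
    )
    cfg.missing_rate_hba1c = 0.0
    cfg.missing_rate_glucose = 0.0
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def _dose_class_utilities(cfg: DgpConfig, hbar: np.ndarray, prev_class: np.ndarray,
                          quarter: int) -> tuple:
    p = cfg.dose_logit_params
    dh = hbar - p.hba1c_ref
    prev_low = prev_class == 1
    prev_high = prev_class == 2
    u_low = (p.intercept_low + p.hba1c_coef_low * dh
             + p.prev_low_on_low * prev_low + p.prev_high_on_low * prev_high
             + p.quarter_trend * quarter)
    u_high = (p.intercept_high + p.hba1c_coef_high * dh
              + p.prev_low_on_high * prev_low + p.prev_high_on_high * prev_high
              + p.quarter_trend * quarter)
    return u_low, u_high


def simulate_cohort(config: DgpConfig) -> pd.DataFrame:
    """Generate a complete (no missingness) person-quarter panel.

    Returns a long-format DataFrame with the columns of
    ``exposure_history.PANEL_COLUMNS``.  Identical seeds give identical
    panels.  Apply :func:`apply_missingness` afterwards for the study-like
    biomarker missingness.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0x5EED])
    n, nq = config.n_subjects, config.n_quarters
    hz = config.hazard_params
    rho = config.ar_coefficient

    age_idx = rng.choice(len(AGE_GROUPS), size=n, p=np.asarray(config.baseline_age_probs))
    eth_idx = rng.choice(len(ETHNICITY_GROUPS), size=n, p=np.asarray(config.ethnicity_probs))
    ses_idx = rng.choice(len(SES_GROUPS), size=n, p=np.asarray(config.ses_probs))
    hba1c0 = rng.normal(config.hba1c0_mean, config.hba1c0_sd, size=n)
    glucose0 = rng.normal(config.glucose0_mean, config.glucose0_sd, size=n)

    hba1c = np.zeros((n, nq))
    glucose = np.zeros((n, nq))
    dose_class = np.zeros((n, nq), dtype=np.int64)
    met = np.zeros((n, nq))
    other = {g: np.zeros((n, nq)) for g in OTHER_GLM_GROUPS}
    other_on = {g: np.zeros(n, dtype=bool) for g in OTHER_GLM_GROUPS}

    # stop bookkeeping: last recorded quarter, and how the history ended
    stop = np.full(n, nq - 1, dtype=np.int64)
    had_event = np.zeros(n, dtype=bool)
    was_censored = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)

    prev_class = np.zeros(n, dtype=np.int64)

    for q in range(nq):
        if not active.any():
            break
        # confounder history: mean HbA1c over the previous (up to) 3 quarters;
        # at quarter 0 the pre-treatment baseline draw plays that role
        if q == 0:
            hbar = hba1c0.copy()
            gbar = glucose0.copy()
        else:
            lo = max(0, q - 3)
            hbar = hba1c[:, lo:q].mean(axis=1)
            gbar = glucose[:, lo:q].mean(axis=1)

        u_low, u_high = _dose_class_utilities(config, hbar, prev_class, q)
        e_low, e_high = np.exp(u_low), np.exp(u_high)
        denom = 1.0 + e_low + e_high
        u = rng.random(n)
        cls = np.where(u < e_high / denom, 2, np.where(u < (e_high + e_low) / denom, 1, 0))
        cls = np.where(active, cls, 0)
        dose_class[:, q] = cls
        met[:, q] = CLASS_MEDIANS[cls]

        # other-GLM groups: start at random, persist once started, 0.5 DDD/day
        for g in OTHER_GLM_GROUPS:
            start = rng.random(n) < config.other_glm_start_prob
            other_on[g] |= start
            other[g][:, q] = np.where(other_on[g] & active, 0.5, 0.0)

        # biomarker AR(1) with steady-state treatment shift per DDD/day
        prev_h = hba1c0 if q == 0 else hba1c[:, q - 1]
        prev_g = glucose0 if q == 0 else glucose[:, q - 1]
        hba1c[:, q] = (config.hba1c0_mean + rho * (prev_h - config.hba1c0_mean)
                       + (1 - rho) * config.treatment_effect_on_hba1c * met[:, q]
                       + rng.normal(0.0, config.hba1c_innovation_sd, size=n))
        glucose[:, q] = (config.glucose0_mean + rho * (prev_g - config.glucose0_mean)
                         + (1 - rho) * config.treatment_effect_on_glucose * met[:, q]
                         + rng.normal(0.0, config.glucose_innovation_sd, size=n))

        # event hazard from the look-back windows (strictly past dose)
        if q >= config.index_quarter:
            lp = np.full(n, hz.base_logit)
            for name, (wa, wb) in WINDOW_LAGS.items():
                seg = met[:, max(0, q - wb): max(0, q - wa + 1)]
                w_avg = seg.sum(axis=1) / (wb - wa + 1)
                lp += getattr(hz, f"beta_{name}") * w_avg
            lp += hz.hba1c_coef * (hbar - hz.hba1c_ref)
            lp += hz.glucose_coef * (gbar - hz.glucose_ref)
            lp += hz.age_coef * (age_idx - hz.age_ref_index)
            with np.errstate(over="ignore"):
                p_event = expit(lp)
            ev = active & (rng.random(n) < p_event)
        else:
            ev = np.zeros(n, dtype=bool)
            rng.random(n)  # keep the stream aligned across index_quarter choices

        cens = active & ~ev & (rng.random(n) < config.censor_hazard)
        newly_stopped = ev | cens
        had_event |= ev
        was_censored |= cens
        stop[newly_stopped] = q
        active &= ~newly_stopped
        prev_class = cls

    # assemble the long panel: quarters 0..stop per subject
    lengths = stop + 1
    sid = np.repeat(np.arange(n), lengths)
    qid = np.concatenate([np.arange(k) for k in lengths])
    flat = sid * nq + qid
    is_last = qid == stop[sid]

    panel = pd.DataFrame(
        {
            "subject_id": sid,
            "quarter": qid,
            "age_group": np.asarray(AGE_GROUPS)[age_idx[sid]],
            "ethnicity": np.asarray(ETHNICITY_GROUPS)[eth_idx[sid]],
            "ses": np.asarray(SES_GROUPS)[ses_idx[sid]],
            "hba1c0": hba1c0[sid],
            "glucose0": glucose0[sid],
            "hba1c": hba1c.ravel()[flat],
            "glucose": glucose.ravel()[flat],
            "metformin_ddd": met.ravel()[flat],
            "at_risk": qid >= config.index_quarter,
            "event": is_last & had_event[sid],
            "censored": is_last & was_censored[sid],
        }
    )
    for g in OTHER_GLM_GROUPS:
        panel[f"{g}_ddd"] = other[g].ravel()[flat]
    return panel[list(PANEL_COLUMNS)]


def apply_missingness(panel: pd.DataFrame, config: DgpConfig) -> pd.DataFrame:
    """Mask quarterly biomarkers missing-at-random at the configured rates.

    HbA1c and glucose are masked independently per subject-quarter.  A
    nonzero ``missing_dose_shift`` tilts the missingness logit by the dose
    class (0/1/2), for MAR stress tests where missingness depends on
    treatment.  Baseline columns (``hba1c0``/``glucose0``) are exempt unless
    ``exempt_baseline_from_missingness`` is False.
    """
    for name in ("missing_rate_hba1c", "missing_rate_glucose"):
        if not 0.0 <= getattr(config, name) <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng([config.seed, 0x315])
    out = panel.copy()
    cls = np.asarray(
        np.where(out["metformin_ddd"] >= 0.5, 2, np.where(out["metformin_ddd"] > 0, 1, 0))
    )
    for col, rate in (("hba1c", config.missing_rate_hba1c),
                      ("glucose", config.missing_rate_glucose)):
        if rate <= 0:
            continue
        if rate >= 1:
            mask = np.ones(len(out), dtype=bool)
        else:
            base_logit = np.log(rate / (1 - rate))
            p = expit(base_logit + config.missing_dose_shift * cls)
            mask = rng.random(len(out)) < p
        out.loc[mask, col] = np.nan
        if not config.exempt_baseline_from_missingness:
            base_mask = rng.random(len(out)) < rate
            out.loc[base_mask, f"{col}0"] = np.nan
    return out


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    """Write a panel as CSV; MISSING encoded as an empty field, flags as 0/1."""
    out = panel.copy()
    for c in ("at_risk", "event", "censored"):
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False, na_rep="")


def read_panel_csv(path) -> pd.DataFrame:
    """Read a panel CSV written by :func:`write_panel_csv`."""
    panel = pd.read_csv(path, float_precision="round_trip")
    for c in ("at_risk", "event", "censored"):
        if c in panel.columns:
            panel[c] = panel[c].astype(bool)
    return panel
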