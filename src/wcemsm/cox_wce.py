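"""Discrete-time proportional-hazards regression with windowed exposure.

The "Cox" analysis is realized as pooled binary regression on the
person-period table: one row per at-risk subject-quarter, event indicator
as outcome, quarter-specific intercepts in place of a baseline hazard.
With a complementary log-log link this is the exact grouped-time
proportional-hazards model, so exponentiated coefficients are hazard
ratios; a logit link is available and nearly identical when events are
rare (<1% per quarter).

Metformin exposure enters as the three window-average doses (per DDD/day);
adjustment covariates are the same three windows for each of the four
other-GLM groups plus baseline age group, ethnicity and socioeconomic
status.  Confidence intervals default to a cluster-robust (sandwich)
covariance clustered on subject, since subjects contribute repeated rows;
the model-based covariance is kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exposure_history import OTHER_GLM_GROUPS, WINDOW_NAMES


class FitError(RuntimeError):
    """Raised when a model fit fails to converge."""


class SeparationError(FitError):
    """Raised when a covariate (quasi-)perfectly predicts the events."""


@dataclass
class FitResult:
    """A fitted pooled regression: coefficients and both covariances."""

    terms: list
    params: np.ndarray
    cov: np.ndarray           # model-based
    cov_robust: np.ndarray    # cluster-robust, clustered on subject
    n_rows: int
    n_events: int
    converged: bool
    loglik: float
    meta: dict = field(default_factory=dict)

    def index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in fit; available: {self.terms}") from None

    def coef(self, term: str) -> float:
        return float(self.params[self.index(term)])

    def se(self, term: str, robust: bool = True) -> float:
        i = self.index(term)
        c = self.cov_robust if robust else self.cov
        return float(np.sqrt(c[i, i]))

    def estimate_table(self, robust: bool = True, level: float = 0.95) -> pd.DataFrame:
        """exp(coefficient) with Wald confidence limits, one row per term."""
        z = norm.ppf(0.5 + level / 2)
        c = self.cov_robust if robust else self.cov
        se = np.sqrt(np.diag(c))
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.params,
                "se": se,
                "estimate": np.exp(self.params),
                "ci_low": np.exp(self.params - z * se),
                "ci_high": np.exp(self.params + z * se),
            }
        )


def _quarter_bin_map(quarters: np.ndarray, events: np.ndarray) -> dict:
    """Map each observed quarter to its intercept bin.

    Quarter-specific intercepts are only estimable for quarters with at
    least one event; a quarter with no events is pooled with the nearest
    preceding event quarter (leading event-free quarters join the first
    event quarter).  This grouped-baseline choice keeps rare-event fits
    away from separation while preserving a step baseline hazard.
    """
    uq = np.unique(quarters)
    ev_by_q = {int(q): 0 for q in uq}
    for q, e in zip(quarters, events):
        if e:
            ev_by_q[int(q)] += 1
    event_quarters = [q for q in sorted(ev_by_q) if ev_by_q[q] > 0]
    if not event_quarters:
        raise FitError("no events in the person-period table; nothing to fit")
    bins, current = {}, event_quarters[0]
    for q in sorted(ev_by_q):
        if ev_by_q[q] > 0:
            current = q
        bins[q] = current
    return bins


def _dummy_block(values: np.ndarray, levels: list, prefix: str) -> tuple:
    cols = [(f"{prefix}[{lv}]", (values == lv).astype(float)) for lv in levels[1:]]
    names = [c[0] for c in cols]
    mat = np.column_stack([c[1] for c in cols]) if cols else np.empty((len(values), 0))
    return mat, names


def build_design(
    rows: pd.DataFrame,
    numeric: list,
    categorical: list,
    quarter_factor: bool = True,
) -> tuple:
    """Design matrix for a pooled person-period fit.

    Returns ``(X, names, meta)`` where ``meta`` carries the quarter-bin map
    and categorical level lists needed to rebuild rows at prediction time.
    Categorical levels are sorted; the first level is the reference.
    """
    n = len(rows)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    meta = {"numeric": list(numeric), "categorical_levels": {}, "quarter_bins": None}

    if quarter_factor:
        q = rows["quarter"].to_numpy(int)
        ev = rows["event"].to_numpy(bool)
        bins = _quarter_bin_map(q, ev)
        meta["quarter_bins"] = bins
        binned = np.array([bins[int(v)] for v in q])
        levels = sorted(set(bins.values()))
        mat, nm = _dummy_block(binned, levels, "quarter")
        blocks.append(mat)
        names += nm
        meta["categorical_levels"]["quarter"] = levels

    for col in categorical:
        levels = sorted(pd.unique(rows[col]).tolist())
        meta["categorical_levels"][col] = levels
        mat, nm = _dummy_block(rows[col].to_numpy(), levels, col)
        blocks.append(mat)
        names += nm

    for col in numeric:
        blocks.append(rows[col].to_numpy(float).reshape(-1, 1))
        names.append(col)

    return np.hstack(blocks), names, meta


_MU_FLOOR = 1e-12


def _inverse_link(link: str, eta: np.ndarray) -> tuple:
    """Mean and its derivative w.r.t. the linear predictor, clipped."""
    eta = np.clip(eta, -30.0, 30.0)
    if link == "logit":
        mu = 1.0 / (1.0 + np.exp(-eta))
        dmu = mu * (1.0 - mu)
    elif link == "cloglog":
        ee = np.exp(eta)
        mu = -np.expm1(-ee)
        dmu = ee * np.exp(-ee)
    else:
        raise ValueError(f"unknown link {link!r}; expected 'logit' or 'cloglog'")
    return np.clip(mu, _MU_FLOOR, 1.0 - _MU_FLOOR), np.maximum(dmu, _MU_FLOOR)


def _bernoulli_loglik(y, mu, w):
    return float(np.sum(w * (y * np.log(mu) + (1.0 - y) * np.log1p(-mu))))


def fit_pooled_binary(
    y: np.ndarray,
    X: np.ndarray,
    names: list,
    groups: np.ndarray,
    link: str = "logit",
    weights: np.ndarray | None = None,
    cluster: bool = True,
    meta: dict | None = None,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> FitResult:
    """Maximum-likelihood pooled binary fit with optional case weights.

    ``link`` is ``"logit"`` or ``"cloglog"``; ``weights`` multiply each
    row's log-likelihood contribution (inverse-probability weights).
    Fitted by Fisher scoring with step-halving (for the logit link this is
    exactly Newton-Raphson); the run-to-run deterministic solver iterates to
    a 1e-10 step tolerance so coefficients are reproducible to the
    optimizer's precision.  The cluster-robust covariance is the sandwich
    over subject-level score sums with a G/(G-1) small-sample factor.
    """
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape[0] != n:
        raise ValueError("weights length does not match the number of rows")

    pbar = float(np.average(y, weights=w))
    if not 0.0 < pbar < 1.0:
        raise FitError("outcome is constant; nothing to fit")
    beta = np.zeros(k)
    beta[names.index("intercept")] = (
        np.log(pbar / (1 - pbar)) if link == "logit" else np.log(-np.log1p(-pbar))
    )

    mu, dmu = _inverse_link(link, X @ beta)
    ll = _bernoulli_loglik(y, mu, w)
    converged = False
    trace = [ll]
    gtol = 1e-9 * max(float(n), 100.0)        # gradient entries scale with n
    for _ in range(maxiter):
        var = mu * (1.0 - mu)
        s = w * (y - mu) * dmu / var          # per-row score factor
        grad = X.T @ s
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        wdiag = w * dmu * dmu / var           # Fisher weights
        H = X.T @ (X * wdiag[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix in the pooled {link} fit "
                "(collinear or separating covariates)"
            ) from exc
        # step-halving keeps Fisher scoring monotone in the log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            mu_c, dmu_c = _inverse_link(link, X @ cand)
            ll_c = _bernoulli_loglik(y, mu_c, w)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        beta, mu, dmu = cand, mu_c, dmu_c
        delta, ll_prev, ll = scale * step, ll, ll_c
        trace.append(ll)
        if np.max(np.abs(delta)) < tol and abs(ll - ll_prev) < 1e-10:
            converged = True
            break
    if not converged:
        raise FitError(
            f"pooled {link} fit did not converge in {maxiter} iterations; "
            f"log-likelihood trace tail: {[round(v, 6) for v in trace[-5:]]}"
        )
    if not np.all(np.isfinite(beta)):
        raise SeparationError("non-finite coefficients; a covariate separates the events")
    if np.max(np.abs(beta)) > 30:
        raise SeparationError(
            "implausibly large coefficient (|beta| > 30); quasi-separation suspected"
        )

    var = mu * (1.0 - mu)
    wdiag = w * dmu * dmu / var
    H = X.T @ (X * wdiag[:, None])
    cov_model = np.linalg.inv(H)
    if cluster:
        s = w * (y - mu) * dmu / var
        scores = X * s[:, None]
        codes, uniques = pd.factorize(np.asarray(groups))
        g = len(uniques)
        cluster_scores = np.zeros((g, k))
        np.add.at(cluster_scores, codes, scores)
        meat = cluster_scores.T @ cluster_scores * (g / max(g - 1, 1))
        cov_robust = cov_model @ meat @ cov_model
    else:
        cov_robust = cov_model
    return FitResult(
        terms=list(names),
        params=beta,
        cov=cov_model,
        cov_robust=cov_robust,
        n_rows=int(n),
        n_events=int(np.sum(y)),
        converged=converged,
        loglik=ll,
        meta=dict(meta or {}, link=link),
    )


def default_cox_terms() -> tuple:
    """(numeric, categorical) adjustment set of the windowed Cox model."""
    numeric = [f"met_{w}_avg" for w in WINDOW_NAMES]
    numeric += [f"{g}_{w}_avg" for g in OTHER_GLM_GROUPS for w in WINDOW_NAMES]
    return numeric, ["age_group", "ethnicity", "ses"]


def fit_discrete_cox(
    rows: pd.DataFrame,
    link: str = "cloglog",
    numeric: list | None = None,
    categorical: list | None = None,
    cluster: bool = True,
) -> FitResult:
    """Fit the discrete-time proportional-hazards model on person-period rows.

    ``rows`` is the table from ``exposure_history.build_analysis_rows``.
    Exponentiated window coefficients are per-DDD hazard ratios.
    """
    default_num, default_cat = default_cox_terms()
    numeric = default_num if numeric is None else list(numeric)
    categorical = default_cat if categorical is None else list(categorical)
    X, names, meta = build_design(rows, numeric, categorical)
    return fit_pooled_binary(
        rows["event"].to_numpy(bool), X, names, rows["subject_id"].to_numpy(),
        link=link, cluster=cluster, meta=meta,
    )


def combine_windows(
    fit: FitResult,
    windows: tuple = ("w2", "w3"),
    prefix: str = "met",
    level: float = 0.95,
    robust: bool = True,
) -> dict:
    """Combined multi-window hazard ratio: the product of per-DDD window HRs.

    On the log scale this is the sum of the window coefficients; the
    confidence interval uses the variance of that sum including the
    coefficient covariances.
    """
    terms = [f"{prefix}_{w}_avg" for w in windows]
    idx = [fit.index(t) for t in terms]
    c = np.zeros(len(fit.terms))
    c[idx] = 1.0
    cov = fit.cov_robust if robust else fit.cov
    log_hr = float(c @ fit.params)
    se = float(np.sqrt(c @ cov @ c))
    z = norm.ppf(0.5 + level / 2)
    return {
        "windows": tuple(windows),
        "log_estimate": log_hr,
        "se": se,
        "estimate": float(np.exp(log_hr)),
        "ci_low": float(np.exp(log_hr - z * se)),
        "ci_high": float(np.exp(log_hr + z * se)),
    }


def combine_hazard_ratios(hrs) -> float:
    """Product of hazard ratios (the multi-window combination rule applied
    to already-published point estimates)."""
    return float(np.prod(np.asarray(hrs, dtype=float)))


def cox_report(fit: FitResult, robust: bool = True) -> pd.DataFrame:
    """Window HR table: the three metformin windows plus their 2-7-year
    combination, shaped like a published hazard-ratio table."""
    tab = fit.estimate_table(robust=robust)
    keep = tab[tab["term"].isin([f"met_{w}_avg" for w in WINDOW_NAMES])].copy()
    label = {"met_w1_avg": "previous year", "met_w2_avg": "years 2-4 before",
             "met_w3_avg": "years 5-7 before"}
    keep["period"] = keep["term"].map(label)
    comb = combine_windows(fit, robust=robust)
    keep = pd.concat(
        [
            keep[["period", "estimate", "ci_low", "ci_high"]],
            pd.DataFrame(
                [{"period": "years 2-7 before", "estimate": comb["estimate"],
                  "ci_low": comb["ci_low"], "ci_high": comb["ci_high"]}]
            ),
        ],
        ignore_index=True,
    )
    return keep
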