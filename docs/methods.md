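# Methods

This note documents the models implemented in `wcemsm`, the assumptions
behind them, the synthetic cohort that drives the test suite, and the
numerical choices that were genuinely open.

## Setting and data structure

The package analyses long-format person-quarter panels: men with incident
diabetes, followed in 3-month intervals ("quarters") indexed from the
diagnosis quarter (quarter 0), with follow-up for prostate cancer starting
at an *index quarter* (default 8, i.e. two years after diagnosis — a
landmark that avoids immortal-time and ascertainment biases around
diagnosis). Each row carries the quarter's average metformin dose in
DDD/day (defined daily dose: the WHO standard adult maintenance dose),
average doses for four other glucose-lowering medication (GLM) groups
(insulins; secretagogues + incretin mimetics; α-glucosidase inhibitors;
thiazolidinediones), quarterly HbA1c (%) and blood glucose (mg/dL) with
missingness, baseline covariates (5-year age group, ethnicity,
socioeconomic status), and event/censoring flags. Purchase records can be
quarterized by dividing the total DDD bought in a quarter by 91.25 days;
the amount purchased is assumed consumed.

## Exposure windows

Dose history enters the outcome models through three piecewise-constant
look-back windows relative to the current quarter `t`: lags 1–4 (previous
year), 5–16 (years 2–4 before) and 17–28 (years 5–7 before). Two covariate
families are computed per window:

* the average DDD/day (continuous; Cox analysis);
* the proportions of window quarters spent in the low (0 < d < 0.5) and
  high (d ≥ 0.5 DDD/day) dose classes (MSM analysis). Class medians of
  0.25 and 0.75 DDD/day represent the nonzero classes.

Three boundary decisions, fixed throughout:

* windows exclude the current quarter (strictly past exposure), so
  same-quarter reverse causation is impossible by construction;
* quarters before diagnosis count as zero dose / class "none", and the
  full nominal window length is always the denominator — covariates are
  continuous in `t` and no special-casing is needed for subjects diagnosed
  fewer than 7 years before `t`;
* the high-dose boundary is inclusive (0.5 → high).

## Discrete-time Cox model

The proportional-hazards analysis is pooled binary regression on the
at-risk person-period rows with quarter-specific intercepts in place of a
baseline hazard. The default complementary log-log link is the exact
grouped-time proportional-hazards model, so exponentiated coefficients are
hazard ratios per DDD/day; a logit link is available and differs
negligibly at the event rates used here (<1% per quarter). The adjustment
set is the three metformin windows, the same three windows for each of the
four other-GLM groups (12 covariates), and the baseline sociodemographics.
Glucose-control markers are deliberately absent: they are simultaneously
confounders and mediators of the dose–cancer relationship, which is what
the weighted MSM addresses.

Multi-window summaries multiply per-DDD hazard ratios (sum the log-HRs),
with the variance of the sum taken from the full coefficient covariance.

## IPW-weighted marginal structural model

A polytomous (3-class) logistic model estimates each quarter's probability
of the received dose class from quarter of follow-up, treatment history,
and the glucose-control confounders (baseline HbA1c and glucose, and their
averages over the previous up-to-3 quarters, computed from whatever values
are non-missing after the chosen missing-data handling; at quarters 0–2
the average runs over the quarters that exist). Treatment history is
encoded as the previous quarter's class plus the cumulative proportions of
prior quarters spent in the low and high classes — four numbers capturing
recency and duration; richer encodings are possible but this one keeps the
weight model low-dimensional. Other-GLM doses are excluded from the weight
model: they are treatment-associated but (in this design) outcome-inert,
and such variables only aggravate positivity problems.

Stabilized weights divide the probability from a numerator model
(quarter, treatment history and the time-invariant sociodemographics) by
the denominator probability and cumulate the ratio from quarter 0 through
the current quarter — cumulation starts at diagnosis even though only
at-risk quarters enter the outcome model. The numerator deliberately
contains only covariates that also appear in the MSM outcome model;
putting baseline biomarkers in the numerator without adjusting for them in
the MSM would invalidate the marginal estimate, so they stay in the
denominator only. Cumulative stabilized weights are truncated to
[0.1, 10.0]. Diagnostics report the mean (≈1 under correct
specification), percentiles, extremes, and the truncated fraction both of
subject-quarters and of subjects (the natural summary is ambiguous, so
both are shown). Denominator probabilities below 1e-6 trigger a positivity
warning listing the offending subject-quarters.

The MSM itself is pooled logistic regression on the at-risk rows in the
weighted population: the six window dose-class proportions, quarter as a
factor, and the baseline sociodemographics. Fitting it with all-ones
weights gives the unweighted comparison analysis.

### Per-DDD conversion and projection

Category log-ORs are converted to a 1-DDD/day scale assuming linearity in
dose. The default is the through-origin least-squares slope of the two
category log-ORs against the class medians,

    slope = (0.25·β_low + 0.75·β_high) / (0.25² + 0.75²),

with delta-method variance; a high-category-only variant (β_high/0.75) is
provided for sensitivity since the exact conversion rule is a genuinely
open choice — both respect the linearity assumption and they coincide when
the category effects are exactly proportional to dose.

Event-free curves under static regimens ("none"/"low"/"high" from the
index quarter onward) evaluate the fitted quarter-specific hazard at a
chosen covariate profile, with window proportions ramping deterministically
as the windows fill, and multiply (1 − hazard) across quarters.

## Missing biomarkers

Three strategies complete the weighting covariates:

* **indicators** — each modelled biomarker covariate (baseline value,
  3-quarter average) is filled with its observed-data mean and gains a 0/1
  missingness indicator that enters the weight model; the fill constant is
  a free choice and the observed mean keeps the filled value neutral;
* **LOCF** — each missing quarterly value is replaced by the subject's most
  recent observed value; subjects with no observed value before their
  first at-risk quarter are dropped (shrinking the cohort, as this method
  does in practice); for kept subjects, quarters before the first
  observation are back-filled with it so the weight model has complete
  rows from quarter 0;
* **time-sequential multiple imputation** — quarters are imputed in time
  order from a normal linear model (previous quarter's value — the
  baseline at quarter 0 — plus current dose class, quarter and baseline
  covariates) with proper posterior draws of the coefficients and residual
  variance per imputation (m = 5 by default); per-imputation fits are
  pooled with Rubin's rules on the log-OR scale.

All three leave observed values untouched, and under 0% missingness all
three reproduce the complete-data fit exactly.

## Synthetic cohort generator

The generator emulates the person-quarter structure above with the causal
feedback loop the MSM exists to handle:

* biomarkers follow Gaussian AR(1) processes (persistence 0.85) whose
  steady-state level is shifted by the current dose (−1% HbA1c and
  −30 mg/dL glucose per DDD/day at the defaults);
* each quarter's dose class is drawn from a 3-category logit given the
  previous class and the mean HbA1c over the previous 3 quarters, with the
  dose set to the class median (0 / 0.25 / 0.75 DDD/day) — the generator's
  treatment is exactly the categorical treatment the weight model
  describes;
* the quarterly event hazard is a logit model in the three window-average
  doses, recent glycaemia and age, so the generator sits inside the model
  family fitted downstream and recovery tests are free of link
  misspecification;
* biomarker missingness is masked per subject-quarter at configurable
  rates (defaults 35% HbA1c, 22% glucose, inside the 25–50% / 20–25%
  bands typical of the claims data this emulates), missing at random by
  default with an optional dose-class tilt for MAR stress tests; baseline
  values are exempt by default;
* death and administrative censoring are collapsed into a single
  noninformative per-quarter censoring hazard (1%).

Magnitudes are illustrative, not calibrated to any real prescribing data,
with two deliberate exceptions chosen while designing the test conditions:
the prescribing response to HbA1c (0.4/0.6 per % on the low/high
utilities) was set so that the stabilized weights reproduce the diagnostic
reported for this design in practice (mean ≈ 1, under 1% of weights
truncated), and the baseline event rate (~0.5%/quarter, log-odds −5.3) is
scaled up from registry-like incidence so that the ~45-parameter MSM has
at least ~5 events per parameter at the simulation sizes the test suite
uses (n = 2000–5000); at registry-scale rates those fits are simply not
estimable at testbed n. Consequences for interpretation: passing tests
demonstrate correctness of the estimators under the stated model, not
realism of Israeli prescribing practice; real data differ in (at least)
continuous dosing, non-MAR laboratory schedules, competing mortality, and
purchase-to-consumption slippage, none of which the generator attempts.

Two preset configurations support the headline simulation checks:

* `null_effect_config` — window effects zero *and* no treatment effect on
  the biomarkers (so there is no mediated pathway and the total effect is
  truly null), while HbA1c still drives both prescribing and the hazard
  (−0.3 log-odds per %): the unweighted MSM is spuriously negative, the
  weighted one is centred on zero;
* `recovery_config` — known window effects (HR 1.5 previous year, 0.6
  years 2–4) with the biomarker→hazard pathway switched off, so the
  windowed fit is unconfounded and should recover the truth.

## Numerical choices

* Pooled binary fits use an in-package Fisher-scoring solver (for the
  logit link this is Newton–Raphson) with step-halving, iterated to a
  1e-10 step / gradient tolerance; coefficients match an independent
  quasi-Newton maximization of the same likelihood to better than 1e-6 and
  statsmodels GLM to ~1e-11 on shared fixtures. The solver exists because
  the Monte-Carlo suites fit thousands of models; it is deterministic
  given the design matrix.
* Quarter-specific intercepts are only estimable for quarters with at
  least one event; event-free quarters are pooled with the nearest
  preceding event quarter (leading event-free quarters join the first
  event quarter). This grouped-baseline choice keeps rare-event fits away
  from separation while preserving a step baseline hazard.
* Separation is detected explicitly (singular information, non-finite or
  implausibly large coefficients) and raised as an error rather than
  returned as a degenerate fit.
* Cluster-robust (sandwich) covariance clustered on subject is computed
  alongside the model-based covariance and is the default for confidence
  intervals — subjects contribute repeated rows, and for weighted fits the
  sandwich is the standard conservative choice. A G/(G−1) small-sample
  factor is applied to the meat.
* The polytomous weight models are statsmodels `MNLogit` fits started at
  zero (deterministic) with reference class "none".
* All randomness flows from integer seeds through `numpy` generators;
  identical seeds give byte-identical panels, reports and imputations.
* Printed tables round to 2 decimals with round-half-even.

## Known limitations

* The piecewise-constant windows are the only weighted-cumulative-exposure
  form implemented; spline-weighted cumulative exposure is out of scope.
* No censoring weights (IPCW): censoring is treated as noninformative,
  matching the generator.
* The regimen projection is for static regimens only; dynamic regimes and
  g-computation are out of scope.
* Confidence intervals are Wald-type; no bootstrap.
* The per-DDD conversion assumes linearity in dose within each window; the
  two implemented variants bracket the reasonable choices but cannot test
  the assumption itself.
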