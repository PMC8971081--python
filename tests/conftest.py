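import pandas as pd
import pytest

import wcemsm as w


@pytest.fixture(scope="session")
def small_cohort():
    """A complete (no missingness) 300-subject panel with default dynamics."""
    cfg = w.default_dgp_config(seed=11)
    cfg.n_subjects = 300
    return w.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_rows(small_cohort):
    return w.build_analysis_rows(small_cohort)


@pytest.fixture(scope="session")
def missing_cohort():
    """A 400-subject panel with study-like biomarker missingness."""
    cfg = w.default_dgp_config(seed=23)
    cfg.n_subjects = 400
    return w.apply_missingness(w.simulate_cohort(cfg), cfg)


def toy_panel(records):
    """Build a minimal panel from (subject, quarter, dose, at_risk, event, censored)."""
    rows = []
    for sid, q, dose, at_risk, event, censored in records:
        rows.append(
            dict(subject_id=sid, quarter=q, age_group="60-64", ethnicity="ashkenazi",
                 ses="low", hba1c0=7.0, glucose0=150.0, hba1c=7.0, glucose=150.0,
                 metformin_ddd=dose, insulin_ddd=0.0, secretagogue_ddd=0.0,
                 agi_ddd=0.0, tzd_ddd=0.0, at_risk=at_risk, event=event,
                 censored=censored)
        )
    return pd.DataFrame(rows)
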