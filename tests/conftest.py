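"""Shared fixtures: minimal hand-built cohorts and small simulated ones."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rptcs.records import SCHEMA_COLUMNS
from rptcs.synthetic import PiecewiseRate, default_config


def make_cohort(
    durations,
    events,
    cancer=None,
    **overrides,
) -> pd.DataFrame:
    """Build a schema-complete cohort from durations and event flags.

    All covariates default to the reference level; ``cancer`` marks which
    deaths are cancer-specific (default: all of them).
    """
    n = len(durations)
    events = list(events)
    cancer = events if cancer is None else list(cancer)
    base = {
        "subject_id": [f"T{i:03d}" for i in range(n)],
        "age_group": "lt65",
        "sex": "male",
        "race": "white",
        "marital_status": "married",
        "fnclcc_grade": "I",
        "size_class": "lt5",
        "multifocality": "no",
        "histology": "SFT",
        "radiation": False,
        "chemotherapy": False,
        "chemoradiotherapy": False,
        "neoadjuvant_radiation": False,
        "surgery_performed": True,
        "primary_tumor": True,
        "extent_of_resection": "complete",
        "followup_months": list(durations),
        "vital_status": ["dead" if e else "alive" for e in events],
        "cancer_specific_death": [bool(e and c) for e, c in zip(events, cancer)],
    }
    base.update(overrides)
    return pd.DataFrame(base, columns=SCHEMA_COLUMNS)


def random_cohort(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Small random cohort with arbitrary censoring and cause mix."""
    durations = rng.integers(0, 40, size=n)
    events = rng.random(n) < 0.6
    cancer = rng.random(n) < 0.7
    return make_cohort(durations, events, events & cancer)


def uncensored_exponential_config(
    rate: float, n: int, seed: int
) -> "rptcs.synthetic.SimulationConfig":
    """Single-cause constant-hazard conditions with no covariate effects
    and effectively no censoring."""
    return default_config(
        n_subjects=n,
        seed=seed,
        baseline_hazard_cancer=PiecewiseRate((0.0,), (rate,)),
        baseline_hazard_other=PiecewiseRate((0.0,), (0.0,)),
        log_hr_cancer={},
        log_hr_other={},
        loss_to_followup_rate=0.0,
        accrual_window_months=1.0,
        admin_cutoff_months=10_000_000.0,
    )


@pytest.fixture
def five_records() -> pd.DataFrame:
    """Censor at 2, deaths at 3 and 3, censor at 5, death at 7."""
    return make_cohort([2, 3, 3, 5, 7], [False, True, True, False, True])


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    from rptcs import generate_cohort

    return generate_cohort(default_config(seed=11))
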