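"""Shared fixtures: a session-scoped synthetic cohort and helpers to build
analysis-row tables directly for survival-model tests."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from glycox.exposure import estimate_all
from glycox.prep import assemble, categorize_glucose
from glycox.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Study-calibrated configuration scaled to 2,500 participants."""
    return replace(default_config(), n_participants=2500, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def analysis_rows(small_config, small_cohort):
    vc, estimates = estimate_all(small_cohort.measurements,
                                 small_config.followup_years)
    return assemble(small_cohort.baselines, estimates, small_cohort.outcomes)


def make_analysis_rows(mu, time_years, event, rng=None, within_sd=None,
                       diabetes=None):
    """Build a minimal analysis-row table around given exposures and outcomes.

    Covariates are filled with neutral constants plus small noise so model-2/3
    designs are full rank; glucose categories derive from ``mu``.
    """
    n = len(mu)
    rng = rng or np.random.default_rng(0)
    mu = np.asarray(mu, dtype=float)
    labels = [categorize_glucose(v) for v in mu]
    from glycox.prep import GLUCOSE_CATEGORIES

    rows = pd.DataFrame(
        {
            "participant_id": [f"S{i:05d}" for i in range(n)],
            "mu_hat": mu,
            "within_sd": within_sd if within_sd is not None else np.nan,
            "glucose_category": labels,
            "category_ordinal": [GLUCOSE_CATEGORIES.index(l) + 1 for l in labels],
            "sd_quartile": pd.array([pd.NA] * n, dtype="Int64"),
            "event": event,
            "time_years": np.asarray(time_years, dtype=float),
            "age": rng.normal(60, 8, n).clip(45),
            "sex": rng.choice(["male", "female"], n),
            "education": rng.choice(["none", "formal"], n),
            "smoking": rng.choice(["never", "current", "former"], n),
            "alcohol": rng.choice(["yes", "no"], n),
            "regular_exercise": rng.choice(["yes", "no"], n),
            "bmi": rng.normal(23.6, 3.0, n),
            "sbp": rng.normal(140, 20, n),
            "dbp": rng.normal(84, 12, n),
            "total_cholesterol": rng.normal(185, 34, n),
            "hypertension": rng.random(n) < 0.5,
            "high_cholesterol": rng.random(n) < 0.3,
            "diabetes": diabetes if diabetes is not None else "none",
        }
    )
    return rows
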