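"""Shared fixtures: published stratum summaries and synthetic cohorts."""

import numpy as np
import pytest

from appsval import CohortSpec, generate_cohort
from appsval.score import builtin_definition

# Published per-category summaries (label, N, hospital mortality %) for the
# original and recalibrated cutoff sets, reference category first, together
# with the odds-ratio columns (point, 2.5 %, 97.5 %) and trend p printed
# alongside them.  These are the worked-example inputs for the association
# analyses.
REFERENCE_STRATA_ORIGINAL = {
    "age": {
        "rows": [("<47", 72, 26.4), ("47-66", 196, 43.9), (">66", 171, 48.0)],
        "odds_ratios": [(2.18, 1.2, 3.95), (2.57, 1.41, 4.7)],
        "p_trend": 0.0046,
    },
    "pf_ratio": {
        "rows": [(">158", 239, 36.4), ("105-158", 135, 46.7), ("<105", 65, 56.9)],
        "odds_ratios": [(1.53, 1.00, 2.35), (2.31, 1.32, 4.03)],
        "p_trend": 0.0015,
    },
    "pmax": {
        "rows": [("<27", 233, 34.8), ("27-30", 48, 25.0), (">33", 134, 52.2)],
        "odds_ratios": [(0.63, 0.31, 1.27), (2.05, 1.33, 3.17)],
        "p_trend": 0.0021,
    },
}

REFERENCE_STRATA_RECALIBRATED = {
    "age": {
        "rows": [("<47", 72, 26.4), ("47-59", 96, 41.7), (">59", 271, 47.2)],
        "odds_ratios": [(1.99, 1.03, 3.87), (2.50, 1.40, 4.44)],
        "p_trend": 0.0021,
    },
    "pf_ratio": {
        "rows": [(">158", 239, 36.4), ("105-158", 135, 46.7), ("<105", 65, 56.9)],
        "odds_ratios": [(1.53, 1.00, 2.35), (2.31, 1.32, 4.03)],
        "p_trend": 0.0015,
    },
    "pmax": {
        "rows": [("<30", 281, 33.1), ("30-33", 40, 45.0), (">33", 94, 55.3)],
        "odds_ratios": [(1.65, 0.85, 3.23), (2.50, 1.55, 4.03)],
        "p_trend": 0.0001,
    },
}

# Published operating characteristics at the Youden cutoff 5.5 on the
# complete cohort, and the cohort composition.
REFERENCE_OPERATING_POINT = {"sens": 0.63, "spec": 0.56, "lr_pos": 1.43, "lr_neg": 0.66}
REFERENCE_COHORT = {"survivors": 252, "deaths": 187, "mortality_pct": 43}


@pytest.fixture(scope="session")
def original_definition():
    return builtin_definition("original")


@pytest.fixture(scope="session")
def recalibrated_definition():
    return builtin_definition("recalibrated")


@pytest.fixture(scope="session")
def study_sized_cohort():
    """A 439-patient synthetic cohort at the default study conditions."""
    return generate_cohort(CohortSpec(n_patients=439, seed=20160915))


@pytest.fixture(scope="session")
def large_cohort():
    """A 10^4-patient cohort with a clear score-mortality gradient."""
    return generate_cohort(CohortSpec(n_patients=10_000, seed=42, mortality_slope=0.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160915)
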