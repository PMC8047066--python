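"""Shared fixtures.

The expensive cohorts (study-sized and recovery-sized) are built once
per session and shared across unit, property and acceptance tests.
Seeds are fixed module constants so every run is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

from wavesick.pipeline import build_cohort_table, simulate_cohort_tables
from wavesick.simulate import preset_config

STRONG_SEED = 1
NULL_SEED = 7
RECOVERY_SEED = 11


def cohort_table(n_subjects, preset, seed, missing=None):
    feats, quest = simulate_cohort_tables(
        n_subjects, missing, preset_config(preset, seed=seed)
    )
    return build_cohort_table(feats, quest)


@pytest.fixture(scope="session")
def strong_tables():
    """Study-sized cohort (28 subjects, one missing P3 -> 83 rows):
    (features, questionnaire) frames, recordings streamed away."""
    return simulate_cohort_tables(28, None, preset_config("strong", seed=STRONG_SEED))


@pytest.fixture(scope="session")
def strong_table(strong_tables):
    return build_cohort_table(*strong_tables)


@pytest.fixture(scope="session")
def null_table():
    """Study-sized cohort with all signal-symptom couplings at zero."""
    return cohort_table(28, "null", NULL_SEED)


@pytest.fixture(scope="session")
def recovery_table():
    """Large strong-coupling cohort (200 subjects, full grid)."""
    return cohort_table(200, "strong", RECOVERY_SEED, missing=[])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
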