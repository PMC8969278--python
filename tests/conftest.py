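"""Shared fixtures: small synthetic cohorts generated at test time."""

import pandas as pd
import pytest

from gaitmat import (CONTROL_PROFILE, MS_LIKE_PROFILE, assemble_feature_rows,
                     generate_cohort, reduce_to_peak, split_passes)


def extract_table(cohort) -> pd.DataFrame:
    """Run a cohort's raw events through the full extraction chain."""
    points = reduce_to_peak(cohort.events)
    recordings = split_passes(points, cohort.metadata)
    return assemble_feature_rows(recordings)


@pytest.fixture(scope="session")
def sd0_cohort():
    """Deterministic-geometry cohort: 2 patients + 2 controls x 2 passes."""
    return generate_cohort(
        n_patients=2, n_controls=2, passes_per_subject=2, seed=3,
        patient_profile=MS_LIKE_PROFILE.with_zero_sd(),
        control_profile=CONTROL_PROFILE.with_zero_sd(),
        between_frac=0.0, within_frac=0.0)


@pytest.fixture(scope="session")
def sd0_table(sd0_cohort):
    return extract_table(sd0_cohort)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort with the default between/within-subject variability."""
    return generate_cohort(n_patients=6, n_controls=4, passes_per_subject=3, seed=1)


@pytest.fixture(scope="session")
def noisy_table(noisy_cohort):
    return extract_table(noisy_cohort)
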