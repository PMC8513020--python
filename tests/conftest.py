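"""Shared fixtures: small synthetic cohorts reused across test modules."""

import pytest

from gaitfatigue import SimulationConfig, build_feature_matrix, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Three participants, short bouts: fast but fully structured."""
    return SimulationConfig(n_participants=3, bout_duration=30.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    """Raw (un-normalized) labeled feature matrix for the small cohort."""
    matrix, events, windows, _ = build_feature_matrix(small_cohort,
                                                      normalize=False)
    return matrix, events, windows


@pytest.fixture(scope="session")
def small_matrix_normalized(small_cohort):
    matrix, _, _, refs = build_feature_matrix(small_cohort, normalize=True)
    return matrix, refs
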