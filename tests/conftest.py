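"""Shared fixtures: small deterministic synthetic cohorts."""

import pytest

from mobilesense.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 enrolled participants, full retention, fixed seed."""
    cfg = SimulationConfig(
        n_participants=12, seed=7,
        p_withdraw=0.0, p_short_data=0.0, p_missing_sensor=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort with the default (study-condition) retention mix."""
    return simulate_cohort(SimulationConfig(n_participants=30, seed=11))
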