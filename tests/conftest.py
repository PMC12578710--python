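import numpy as np
import pytest

from hybridchoice import ModelParams, generate_schedule, make_cohort, simulate_agent

#: group-median parameter point used throughout the recovery tests
STUDY_PARAMS = ModelParams(omega_mult=0.49, omega_p=0.82, tau=14.56)


@pytest.fixture(scope="session")
def schedule_500():
    return generate_schedule(500, seed=123)


@pytest.fixture(scope="session")
def schedule_200():
    return generate_schedule(200, seed=7)


@pytest.fixture(scope="session")
def study_session(schedule_500):
    """One 500-trial session simulated at the group-median parameters."""
    return simulate_agent(schedule_500, STUDY_PARAMS, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 3 drugs x 80 trials, zero drug shifts."""
    return make_cohort(n_subjects=6, n_trials=80, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
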