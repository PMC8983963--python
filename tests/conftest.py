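import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import roastair as ra

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_design():
    return ra.reference_design()


@pytest.fixture(scope="session")
def noiseless_trial(ref_design):
    """Synthetic trial with known truth (ef0=2, ef_ss=0.5, k=1), no noise."""
    truth = ra.TrueEmissionParams(ef0=2.0, ef_ss=0.5, k=1.0, seed=0, noise_cv=0.0)
    return ra.gen_chamber_series(ref_design, truth), truth


@pytest.fixture(scope="session")
def scenario_a_profile():
    schedule = ra.scenario_a()
    system = ra.default_system("scenario_A")
    return ra.simulate_schedule(schedule, system)


@pytest.fixture(scope="session")
def scenario_b_profile():
    schedule = ra.scenario_b()
    system = ra.default_system("scenario_B")
    return ra.simulate_schedule(schedule, system)
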