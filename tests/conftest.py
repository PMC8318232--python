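import numpy as np
import pytest
from hypothesis import settings

from riskbandit import MODELS, build_schedule

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from riskbandit.models import simulate_session


@pytest.fixture(scope="session")
def standard_schedule():
    """One balanced 4-block, 480-trial schedule (fixed seed)."""
    return build_schedule(4, 10, seed=101)


@pytest.fixture(scope="session")
def rw_session(standard_schedule):
    """A session simulated from the RW model at its documented defaults."""
    session, trace = simulate_session(
        "RW", MODELS["RW"].defaults, schedule=standard_schedule, seed=7
    )
    return session, trace


@pytest.fixture(scope="session")
def peirs_session(standard_schedule):
    session, trace = simulate_session(
        "PEIRS", MODELS["PEIRS"].defaults, schedule=standard_schedule, seed=7
    )
    return session, trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
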