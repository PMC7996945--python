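import numpy as np
import pytest
from hypothesis import settings

from gstchunks import GeneratorParams, GridTask, simulate_session, with_params

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_task() -> GridTask:
    return GridTask()


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams()


@pytest.fixture(scope="session")
def quiet_session(default_task, default_params):
    """One error-free, moderately sized session for cheap analysis tests."""
    params = with_params(default_params, error_rate_initial=0.0,
                         n_successful_trials=20)
    return simulate_session(default_task, params, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
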