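import numpy as np
import pytest

from groupbandit import SimpleParams, TaskConfig, build_schedule, simulate_agent_session


@pytest.fixture(scope="session")
def default_task() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def default_schedule(default_task):
    return build_schedule(default_task)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def example_session():
    """One deterministic 100-trial simulated session for reuse."""
    return simulate_agent_session(SimpleParams(alpha=0.6, beta=5.0), rng=12345)


def random_session_arrays(rng, n_trials=100):
    """A random (choices, rewards) pair with no model structure."""
    return rng.integers(0, 2, n_trials), rng.integers(0, 2, n_trials)
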