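import numpy as np
import pytest

from vmrsim.learners import LearnerParams, LearnerState
from vmrsim.plant import PlantParams, min_jerk_trajectory, inverse_dynamics


@pytest.fixture(scope="session")
def plant():
    return PlantParams()


@pytest.fixture(scope="session")
def desired(plant):
    return min_jerk_trajectory(plant)


@pytest.fixture(scope="session")
def u0(desired, plant):
    return inverse_dynamics(desired, plant)


@pytest.fixture
def replay_state(plant):
    """Learner that replays the fallback commands: no learning, no feedback."""
    lp = LearnerParams(L=((0.0,) * 4,) * 2, p=0.0, feedback_on=False)
    return LearnerState(plant, lp)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
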