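import numpy as np
import pytest
from hypothesis import settings

from hfmaze import SimConfig, generate_hole_layout, simulate_cohort
from hfmaze.config import PipelineConfig

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return generate_hole_layout(seed=1)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_static_dataset(layout):
    """4 mice x 5 trials, static entrance: cheap cohort shared across tests."""
    return simulate_cohort(SimConfig(n_mice=4, n_trials=5, seed=11), layout)


def straight_trajectory(start, end, duration=10.0, rate=30.0, meta=None):
    from hfmaze.trajectory import Trajectory, TrialMeta

    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    frac = t / duration
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    xy = start[None, :] + frac[:, None] * (end - start)[None, :]
    return Trajectory(t=t, x=xy[:, 0], y=xy[:, 1], metadata=meta or TrialMeta())


@pytest.fixture
def make_straight():
    return straight_trajectory
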