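import numpy as np
import pytest

from crossgaze.metrics import compute_metrics_table
from crossgaze.observer import default_participants, generate_dataset
from crossgaze.scene import DesignGrid, SceneConfig, TrialSpec, make_trajectory


@pytest.fixture(scope="session")
def scene():
    return SceneConfig()


@pytest.fixture(scope="session")
def grid():
    return DesignGrid()


@pytest.fixture(scope="session")
def standard_trial():
    return TrialSpec("p01", "speed", 0, 0, 50.0, 3.04, True, "right")


@pytest.fixture(scope="session")
def standard_traj(scene):
    return make_trajectory(50.0, 3.04, "right", scene, 1000.0)


@pytest.fixture(scope="session")
def small_dataset(scene, grid):
    """Desk-scale cohort: 10 distinct observers, 1 block per task, 100 Hz.

    Shared across classification and acceptance tests; built once.
    """
    participants = default_participants(10, seed=11)
    return generate_dataset(participants, seed=12, scene=scene, grid=grid,
                            gaze_sample_rate=100.0, n_blocks=1)


@pytest.fixture(scope="session")
def small_metrics(small_dataset):
    return compute_metrics_table(small_dataset, window="feature")
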