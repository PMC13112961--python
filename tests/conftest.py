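import numpy as np
import pytest

from sdnet.arm import ArmParameters, ManipulandumParameters
from sdnet.datasets import build_dataset
from sdnet.simulate import TaskConfig, default_neurons, generate_sessions


@pytest.fixture(scope="session")
def arm():
    return ArmParameters()


@pytest.fixture(scope="session")
def manip():
    return ManipulandumParameters()


@pytest.fixture(scope="session")
def tiny_task():
    """Small but complete task: 3 sessions x 2 units, 8 targets, 6 reps."""
    return TaskConfig(n_sessions=3, trials_per_target=6, neurons_per_session=2,
                      outlier_fraction=0.0, cocontraction_amplitude=0.05)


@pytest.fixture(scope="session")
def tiny_sessions(tiny_task):
    return generate_sessions(tiny_task, master_seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sessions, tiny_task):
    return build_dataset(tiny_sessions, tiny_task)
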