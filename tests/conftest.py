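import numpy as np
import pytest

from domeq import (
    BackgroundModel,
    BiGaussianModel,
    DistanceGrid,
    PathwayModel,
    make_two_domain_system,
    simulate_trace,
    truth_to_measurements,
)
from domeq.synthetic import NoiseConfig


@pytest.fixture(scope="session")
def grid():
    return DistanceGrid()


@pytest.fixture(scope="session")
def time_axis():
    return np.linspace(0.0, 2.5, 251)


@pytest.fixture(scope="session")
def apo_model():
    """Two-state mixture with the canonical apo geometry: compact at 22 A
    (sigma 1.5), extended at 45 A (sigma 8), 68% compact."""
    return BiGaussianModel(22.0, 1.5, 0.68, 45.0, 8.0)


@pytest.fixture(scope="session")
def apo_trace(apo_model, time_axis):
    return simulate_trace(apo_model, PathwayModel.four_pulse(0.4),
                          BackgroundModel(0.1, 1.0), time_axis)


@pytest.fixture(scope="session")
def truth():
    return make_two_domain_system(seed=0)


@pytest.fixture(scope="session")
def noiseless_measurements(truth):
    return truth_to_measurements(truth, NoiseConfig(0.0, 0.0), seed=1)
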