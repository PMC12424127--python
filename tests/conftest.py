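import numpy as np
import pytest

from chemokin.gradient import GradientSource
from chemokin.presets import get_preset
from chemokin.walks import MotilityParams, Trajectory


@pytest.fixture
def source():
    """Pulsed ADP source at the origin with default physics."""
    return GradientSource(tip_position=(0.0, 0.0))


@pytest.fixture
def control():
    return get_preset("control")


@pytest.fixture
def unbiased_params():
    """No gradient coupling, no persistence: an isotropic random walk."""
    return MotilityParams(chemotactic_sensitivity=0.0, persistence=0.0)


def make_track(points, dt=15.0, cell_id=0):
    """Trajectory from a list of (x, y) points at uniform spacing."""
    pts = np.asarray(points, dtype=float)
    return Trajectory(cell_id=cell_id, times=np.arange(len(pts)) * dt, positions=pts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
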