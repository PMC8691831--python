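import numpy as np
import pytest

from cleavekit.geometry2d import Contour
from cleavekit.shape_models import ShapeSpec, make_shape
from cleavekit.spindle_metrics import AxisFrame


@pytest.fixture
def unit_square():
    return Contour([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def frame_up():
    """Canonical frame: AV axis = +y, positive tilt side = +x."""
    return AxisFrame(origin=(0, 0), av_direction=(0, 1), sign_reference=(1, 0))


@pytest.fixture
def circle720():
    return make_shape(ShapeSpec("circle", radius=10.0, n_vertices=720))


@pytest.fixture
def half_disc():
    """Unit half-disc, flat edge along the AV (y) axis, arc toward +x."""
    return make_shape(ShapeSpec("half_disc", radius=1.0, n_vertices=720))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
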