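import numpy as np
import pytest

from fetrad.features import discretize
from fetrad.quantify import PETVolume


@pytest.fixture
def volume_factory():
    """Build a PETVolume from a (possibly 2D) array placed in a 3D grid."""

    def build(plane, background=1.0, shape=None, spacing=(1.0, 1.0, 1.0)):
        plane = np.asarray(plane, dtype=float)
        if shape is None:
            shape = (plane.shape[0] + 4, plane.shape[1] + 4, 3)
        data = np.full(shape, background, dtype=float)
        data[2:2 + plane.shape[0], 2:2 + plane.shape[1], 1] = plane
        return PETVolume(data, spacing=spacing, units="SUV")

    return build


@pytest.fixture
def droi_factory():
    """Discretize an integer level pattern directly (levels act as TBR/0.1)."""

    def build(pattern, mask=None):
        pattern = np.asarray(pattern, dtype=float)
        if mask is None:
            mask = np.ones_like(pattern, dtype=bool)
        # place level k at the center of bin k: value = (k - 0.5) * w
        values = (pattern - 0.5) * 0.1
        return discretize(values, np.asarray(mask, dtype=bool), bin_width=0.1)

    return build
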