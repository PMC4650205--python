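import numpy as np
import pytest

from leafroll import ShapeSpec, make_shape


@pytest.fixture
def semicircle_r2():
    """Noise-free semicircle of radius 2 mm, 35 points (kappa = 0.5)."""
    return make_shape(
        ShapeSpec(kind="arc", length=2 * np.pi, kappa=0.5, n_points=35)
    )


@pytest.fixture
def straight_line():
    """Noise-free 10 mm straight strip, 35 points."""
    return make_shape(ShapeSpec(kind="line", length=10.0, n_points=35))


def rigid_motion(points, angle, shift):
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return points @ R.T + np.asarray(shift)
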