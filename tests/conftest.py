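import numpy as np
import pytest

from nltvfdk import ConeBeamGeometry, Ellipsoid, EllipsoidPhantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geom():
    """Tiny scan for fast forward/backprojection tests."""
    return ConeBeamGeometry.circular(4, n_u=16, n_v=16, pitch_u=8.0, pitch_v=8.0)


@pytest.fixture
def sphere_phantom():
    """Centered 10 mm water-like sphere."""
    return EllipsoidPhantom((Ellipsoid((0.0, 0.0, 0.0), (10.0, 10.0, 10.0), 0.0, 0.02),))
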