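import numpy as np
import pytest

from dyncbct.geometry import ScanGeometry, VolumeGrid, build_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry():
    """A small full-fan 360-degree scan geometry."""
    angles, ts = build_trajectory(10.0, 360.0, 3.6)  # 36 frames
    return ScanGeometry(1000.0, 1500.0, 48, 32, 8.0, 8.0, angles, ts)


@pytest.fixture
def sphere_volume():
    """A uniform sphere (radius 80 mm, mu = 0.02 / mm) on a 64^3 grid."""
    vol = VolumeGrid.empty((64, 64, 64), 4.0)
    pts = vol.voxel_centers().reshape(64, 64, 64, 3)
    vol.values[:] = (np.linalg.norm(pts, axis=-1) <= 80.0) * 0.02
    return vol
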