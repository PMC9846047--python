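import numpy as np
import pytest

from tmstarget import (
    CPCCoordinate,
    VoxelGrid,
    make_head,
)
from tmstarget.synthetic import GridSpec, HeadSpec, make_shell_grid


@pytest.fixture(scope="session")
def unit_head():
    """Unit-radius analytic sphere head (level-4 icosphere) with equator landmarks."""
    return make_head(HeadSpec(radius_mm=1.0, subdivisions=4))


@pytest.fixture(scope="session")
def coarse_head():
    """Coarser copy of the unit head for convergence comparisons."""
    return make_head(HeadSpec(radius_mm=1.0, subdivisions=3))


@pytest.fixture(scope="session")
def head85():
    """Head-sized sphere (85 mm) at working resolution."""
    return make_head(HeadSpec(radius_mm=85.0, subdivisions=3))


@pytest.fixture(scope="session")
def shell_grid():
    """Small gray-matter shell grid under the 85 mm head."""
    return make_shell_grid(HeadSpec(radius_mm=85.0), GridSpec(voxel_size_mm=8.0))


@pytest.fixture
def cube_grid():
    """4x4x4 full-mask grid with a 2 mm isotropic affine."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return VoxelGrid((4, 4, 4), affine, np.ones((4, 4, 4), bool))


def sphere_cpc_oracle(p_nz: float, p_al: float, radius: float = 1.0) -> np.ndarray:
    """Closed-form CPC forward map on a sphere with equator landmarks.

    The sagittal curve is the x=0 meridian from NZ=(0,r,0) over the apex to
    IZ=(0,-r,0); the coronal curve through its point q is the great circle
    through AL=(-r,0,0), AR=(r,0,0) and q.
    """
    phi = p_nz * np.pi
    u = np.array([0.0, np.cos(phi), np.sin(phi)])
    e1 = np.array([1.0, 0.0, 0.0])
    return radius * (-np.cos(p_al * np.pi) * e1 + np.sin(p_al * np.pi) * u)
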