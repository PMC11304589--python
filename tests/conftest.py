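import math

import numpy as np
import pytest

from memphase import AxisymGrid, ElasticParams, ScalarField


@pytest.fixture(scope="session")
def params():
    """Reference elastic parameters: k = 20 kBT, kG = −k, ϵ = 1 (lengths in
    units of the interface parameter)."""
    return ElasticParams(k=20.0, kG=-20.0, m=0.0, eps=1.0)


@pytest.fixture(scope="session")
def small_grid():
    return AxisymGrid(r_max=12.0, z_min=-6.0, z_max=6.0, nr=25, nz=25)


@pytest.fixture(scope="session")
def bumpy_field(small_grid):
    """A smooth, deliberately non-equilibrium field for derivative tests."""
    R, Z = small_grid.meshgrid()
    vals = np.tanh((4.0 - np.sqrt(R**2 + Z**2)) / math.sqrt(2.0))
    vals = vals + 0.05 * np.sin(R) * np.cos(Z)
    return ScalarField(small_grid, vals)


@pytest.fixture(scope="session")
def smooth_direction(small_grid):
    R, Z = small_grid.meshgrid()
    return np.exp(-((R - 3.0) ** 2 + Z**2) / 4.0)


def sphere_field(radius, params, spacing=0.5, clearance=8.0):
    from memphase import ShapeSpec, make_grid_for_shape, make_shape

    spec = ShapeSpec(kind="sphere", radius=radius)
    grid = make_grid_for_shape(spec, params, clearance=clearance,
                               spacing=spacing)
    return make_shape(spec, grid, params)
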