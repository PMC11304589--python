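"""Shape fixtures and level-set diagnostics."""

import math

import numpy as np
import pytest

from memphase import (
    ScalarField,
    ShapeSpec,
    energy_breakdown,
    interface_band,
    make_grid_for_shape,
    make_shape,
    membrane_separation,
    tanh_from_distance,
)
from memphase.shapes import (
    BAND_HALF_WIDTH,
    oblate_aspect_for_reduced_volume,
    reduced_volume_spheroid,
    spheroid_area_volume,
)

SQRT2 = math.sqrt(2.0)


def test_tanh_from_distance_closed_form(params, small_grid):
    d = np.full(small_grid.shape, SQRT2 * params.eps)
    f = tanh_from_distance(ScalarField(small_grid, d), params)
    assert f.values == pytest.approx(math.tanh(1.0))
    zero = tanh_from_distance(ScalarField(small_grid, np.zeros(small_grid.shape)),
                              params)
    assert zero.values == pytest.approx(0.0, abs=1e-15)
    deep = tanh_from_distance(ScalarField(small_grid,
                                          np.full(small_grid.shape, -40.0)),
                              params)
    assert deep.values == pytest.approx(-1.0, abs=1e-12)


def test_spheroid_geometry_helpers():
    A, V = spheroid_area_volume(2.0, 2.0)  # sphere of radius 2
    assert A == pytest.approx(16.0 * math.pi)
    assert V == pytest.approx(32.0 * math.pi / 3.0)
    assert reduced_volume_spheroid(1.0) == pytest.approx(1.0)
    x = oblate_aspect_for_reduced_volume(0.71)
    assert 0.0 < x < 1.0
    assert reduced_volume_spheroid(x) == pytest.approx(0.71, abs=1e-10)


def test_sphere_fixture_reduced_volume(params):
    spec = ShapeSpec(kind="sphere", radius=25.0)
    grid = make_grid_for_shape(spec, params, spacing=0.5)
    bd = energy_breakdown(make_shape(spec, grid, params), params)
    assert bd.v == pytest.approx(1.0, abs=0.01)


def test_clifford_torus_reduced_volume(params):
    spec = ShapeSpec(kind="clifford_torus", Dve=80.0)
    grid = make_grid_for_shape(spec, params, spacing=0.5)
    bd = energy_breakdown(make_shape(spec, grid, params), params)
    assert bd.v == pytest.approx(0.71, abs=0.01)
    assert bd.Dve == pytest.approx(80.0, rel=0.02)


def test_two_spheres_reduced_volume(params):
    """Two equal far-apart spheres: v = (2R³)/(2R²)^{3/2} = 1/√2."""
    spec = ShapeSpec(kind="two_spheres", radius=20.0, gap=8.0)
    grid = make_grid_for_shape(spec, params, spacing=0.5)
    bd = energy_breakdown(make_shape(spec, grid, params), params)
    assert bd.v == pytest.approx(1.0 / SQRT2, abs=0.01)


def test_oblate_fixture_hits_target_v(params):
    spec = ShapeSpec(kind="ellipsoid", v=0.71, Dve=80.0)
    grid = make_grid_for_shape(spec, params, spacing=0.5)
    bd = energy_breakdown(make_shape(spec, grid, params), params)
    assert bd.v == pytest.approx(0.71, abs=0.01)
    assert bd.A == pytest.approx(math.pi * 80.0**2, rel=0.02)


def test_shape_domain_guards(params):
    spec = ShapeSpec(kind="sphere", radius=30.0)
    small = make_grid_for_shape(ShapeSpec(kind="sphere", radius=10.0), params)
    with pytest.raises(ValueError, match="clearance"):
        make_shape(spec, small, params)
    with pytest.raises(ValueError, match="3ϵ|3ϵ|radii"):
        make_shape(ShapeSpec(kind="sphere", radius=2.0), small, params)


def test_interface_band_planar_and_sphere(params):
    from memphase import AxisymGrid

    g = AxisymGrid(r_max=10.0, z_min=-8.0, z_max=8.0, nr=41, nz=65)
    _, Z = g.meshgrid()
    planar = ScalarField(g, np.tanh(-Z / (SQRT2 * params.eps)))
    outer, inner = interface_band(planar, params)
    assert len(outer) == 1 and len(inner) == 1
    # bands sit at z = ±(3/√2)ϵ
    assert np.allclose(outer[0][:, 1], BAND_HALF_WIDTH, atol=0.05)
    assert np.allclose(inner[0][:, 1], -BAND_HALF_WIDTH, atol=0.05)

    spec = ShapeSpec(kind="sphere", radius=10.0)
    grid = make_grid_for_shape(spec, params, spacing=0.5)
    sph = make_shape(spec, grid, params)
    outer, inner = interface_band(sph, params)
    r_out = np.hypot(outer[0][:, 0], outer[0][:, 1]).mean()
    r_in = np.hypot(inner[0][:, 0], inner[0][:, 1]).mean()
    assert r_out == pytest.approx(10.0 + BAND_HALF_WIDTH, abs=0.05)
    assert r_in == pytest.approx(10.0 - BAND_HALF_WIDTH, abs=0.05)

    empty = ScalarField(g, -np.ones(g.shape))
    outer, inner = interface_band(empty, params)
    assert outer == [] and inner == []


def test_membrane_separation_two_spheres(params):
    R, gap = 10.0, 9.0
    spec = ShapeSpec(kind="two_spheres", radius=R, gap=gap)
    grid = make_grid_for_shape(spec, params, spacing=0.5)
    phi = make_shape(spec, grid, params)
    sep = membrane_separation(phi, params)
    expected = gap - 2.0 * BAND_HALF_WIDTH * params.eps
    assert sep == pytest.approx(expected, abs=0.15)

    single = make_shape(ShapeSpec(kind="sphere", radius=R),
                        make_grid_for_shape(ShapeSpec(kind="sphere", radius=R),
                                            params, spacing=0.5), params)
    with pytest.raises(ValueError, match="fewer than two"):
        membrane_separation(single, params)
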