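"""Energy functionals: closed-form identities, sharp-interface limits and
the exactness of the hand-written discrete gradients."""

import math

import numpy as np
import pytest

from memphase import (
    ElasticParams,
    MonolayerParams,
    ScalarField,
    area_functional,
    bending_energy,
    energy_breakdown,
    force_field,
    functional_derivative,
    gaussian_energy,
    genus_from_gaussian,
    kg_from_monolayer,
    psi_b,
    volume_functional,
)
from memphase.energetics import discrete_gradient, energy_operators

from conftest import sphere_field

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# parameter containers


def test_elastic_params_validation():
    with pytest.raises(ValueError):
        ElasticParams(k=-1.0, kG=0.0)
    with pytest.warns(UserWarning):
        ElasticParams(k=10.0, kG=-25.0)  # kG/k outside [-2, 0]
    p = ElasticParams(k=20.0, kG=-20.0)
    assert p.thickness == pytest.approx(5.0)  # 6 eps = 5 nm


def test_kg_from_monolayer():
    assert kg_from_monolayer(
        MonolayerParams(k_ml=7.0, kG_ml=-3.0, z0=1.0, m_ml=0.0)) == -6.0
    # k_ml=10, z0=2, m_ml=-0.05, kG_ml=-8 -> 2(-8 + 1) = -14
    assert kg_from_monolayer(
        MonolayerParams(k_ml=10.0, kG_ml=-8.0, z0=2.0, m_ml=-0.05)
    ) == pytest.approx(-14.0)
    # more negative monolayer spontaneous curvature raises kG (fusogenic)
    vals = [kg_from_monolayer(MonolayerParams(10.0, -8.0, 2.0, m))
            for m in (-0.1, -0.05, 0.0, 0.05)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_genus_from_gaussian():
    kG = -20.0
    assert genus_from_gaussian(4.0 * math.pi * kG, kG)[0] == 0
    assert genus_from_gaussian(0.0, kG) == (1, 0.0)
    assert genus_from_gaussian(-4.0 * math.pi * kG, kG)[0] == 2
    with pytest.raises(ValueError):
        genus_from_gaussian(1.0, 0.0)


# ---------------------------------------------------------------------------
# pointwise densities and uniform-field limits


def test_psi_b_uniform_and_planar(params, small_grid):
    ones = ScalarField(small_grid, np.ones(small_grid.shape))
    assert np.abs(psi_b(ones, params).values).max() < 1e-12

    pm = ElasticParams(k=20.0, kG=-20.0, m=0.05, eps=1.0)
    zeros = ScalarField(small_grid, np.zeros(small_grid.shape))
    expected = SQRT2 * pm.m / pm.eps  # only the reaction term survives
    assert psi_b(zeros, pm).values == pytest.approx(expected)

    # planar tanh solves the 1D Euler-Lagrange equation
    _, Z = small_grid.meshgrid()
    planar = ScalarField(small_grid, np.tanh(-Z / SQRT2))
    assert np.abs(psi_b(planar, params).values[2:-2, 2:-2]).max() < 5e-3
    assert bending_energy(planar, params) < 1e-3 * 8 * math.pi * params.k


def test_uniform_fields_have_no_area_volume_energy(params, small_grid):
    ones = ScalarField(small_grid, np.ones(small_grid.shape))
    minus = ScalarField(small_grid, -np.ones(small_grid.shape))
    assert abs(gaussian_energy(ones, params)) < 1e-30
    assert area_functional(ones, params) < 1e-12
    assert volume_functional(minus) == pytest.approx(0.0, abs=1e-12)
    # phi = +1 fills the whole domain
    g = small_grid
    domain = math.pi * g.r_max**2 * (g.z_max - g.z_min)
    assert volume_functional(ones) == pytest.approx(domain, rel=1e-10)


def test_planar_interface_area(params):
    """A flat tanh interface spanning a cylinder recovers the disk area:
    the 1D profile integral of the area density is exactly 1."""
    from memphase import AxisymGrid

    g = AxisymGrid(r_max=10.0, z_min=-8.0, z_max=8.0, nr=51, nz=81)
    _, Z = g.meshgrid()
    planar = ScalarField(g, np.tanh(-Z / (SQRT2 * params.eps)))
    assert area_functional(planar, params) == pytest.approx(
        math.pi * 100.0, rel=1e-2)


# ---------------------------------------------------------------------------
# sharp-interface limits on the sphere fixture


def test_sphere_energetics_sharp_limit(params):
    """Sphere at λ = 0.02: EB → 8πk, EG → 4πkG, A → 4πR², V → (4/3)πR³."""
    R = 25.0
    phi = sphere_field(R, params, spacing=0.5)
    bd = energy_breakdown(phi, params)
    assert bd.EB == pytest.approx(8.0 * math.pi * params.k, rel=0.01)
    assert bd.EG == pytest.approx(4.0 * math.pi * params.kG, rel=0.01)
    assert bd.A == pytest.approx(4.0 * math.pi * R**2, rel=0.01)
    assert bd.V == pytest.approx(4.0 / 3.0 * math.pi * R**3, rel=0.01)
    assert bd.v == pytest.approx(1.0, abs=0.01)
    assert bd.Dve == pytest.approx(2.0 * R, rel=0.01)
    assert bd.E == bd.EB + bd.EG


def test_scale_invariance(params):
    """Doubling the vesicle size changes E/8πk only at O(λ²)."""
    e1 = energy_breakdown(sphere_field(25.0, params, spacing=0.5), params)
    e2 = energy_breakdown(sphere_field(50.0, params, spacing=0.5), params)
    s = 8.0 * math.pi * params.k
    assert abs(e1.E / s - e2.E / s) < 0.01


def test_translation_neutrality(params):
    """Translating an isolated vesicle along z leaves E unchanged."""
    from memphase import ShapeSpec, make_grid_for_shape, make_shape
    import dataclasses

    spec = ShapeSpec(kind="sphere", radius=10.0)
    grid = make_grid_for_shape(spec, params, clearance=14.0, spacing=0.5)
    e0 = energy_breakdown(make_shape(spec, grid, params), params).E
    spec2 = dataclasses.replace(spec, center_z=2.0)
    e1 = energy_breakdown(make_shape(spec2, grid, params), params).E
    assert abs(e1 - e0) < 1e-3 * 8.0 * math.pi * params.k


# ---------------------------------------------------------------------------
# discrete gradients: the directional-derivative contract


def _functional(which, params):
    return {
        "bending": lambda f: bending_energy(f, params),
        "gaussian": lambda f: gaussian_energy(f, params),
        "area": lambda f: area_functional(f, params),
        "volume": lambda f: volume_functional(f),
        "total": lambda f: bending_energy(f, params) + gaussian_energy(f, params),
    }[which]


@pytest.mark.parametrize("which", ["bending", "gaussian", "area", "volume",
                                   "total"])
def test_directional_derivative_exactness(which, params, bumpy_field,
                                          smooth_direction):
    """⟨∂F/∂ϕ, δ⟩ matches the central finite difference of the discretized
    functional, with the O(h²) error of the difference itself."""
    ops = energy_operators(bumpy_field.grid)
    g = discrete_gradient(bumpy_field.values.ravel(), ops, params, which)
    inner = float(g @ smooth_direction.ravel())
    F = _functional(which, params)

    def fd(h):
        up = ScalarField(bumpy_field.grid, bumpy_field.values + h * smooth_direction)
        dn = ScalarField(bumpy_field.grid, bumpy_field.values - h * smooth_direction)
        return (F(up) - F(dn)) / (2.0 * h)

    err1 = abs(fd(1e-4) - inner)
    err2 = abs(fd(5e-5) - inner)
    scale = max(abs(inner), 1.0)
    assert err1 < 1e-6 * scale
    # O(h²): quartering (within roundoff slack)
    assert err2 < 0.5 * err1 + 1e-9 * scale


def test_functional_derivative_weighted_inner_product(params, bumpy_field,
                                                      smooth_direction):
    """δF/δϕ (continuum scaling) reproduces the same directional derivative
    through the weighted inner product, axis nodes included."""
    from memphase.grid import get_operators

    fd_field = functional_derivative(bumpy_field, params, "area")
    w = get_operators(bumpy_field.grid).weights
    inner_w = float(w @ (fd_field.values.ravel() * smooth_direction.ravel()))
    ops = energy_operators(bumpy_field.grid)
    g = discrete_gradient(bumpy_field.values.ravel(), ops, params, "area")
    assert inner_w == pytest.approx(float(g @ smooth_direction.ravel()),
                                    rel=1e-12)
    assert np.all(np.isfinite(fd_field.values))


def test_force_field_zero_on_uniform(params, small_grid):
    ones = ScalarField(small_grid, np.ones(small_grid.shape))
    f = force_field(ones, params)
    assert np.abs(f.vr).max() < 1e-20
    assert np.abs(f.vz).max() < 1e-20
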