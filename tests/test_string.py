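"""String method mechanics: path construction, reparametrization and the
energy-profile analysis (with a brute-force oracle)."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memphase import (
    ConstraintSet,
    ScalarField,
    ShapeSpec,
    StringOptions,
    StringPath,
    analyze_path,
    init_path,
    make_grid_for_shape,
    make_shape,
    reparametrize,
    run_string,
)
from memphase.energetics import EnergyBreakdown
from memphase.grid import get_operators
from memphase.relax import relax


@pytest.fixture(scope="module")
def sphere_endpoints(params):
    """Two relaxed spheres displaced along z: a pure-translation path."""
    spec = ShapeSpec(kind="sphere", radius=10.0, center_z=-4.0)
    grid = make_grid_for_shape(spec, params, clearance=12.0, spacing=2.0 / 3.0)
    phiA = make_shape(spec, grid, params)
    phiB = make_shape(dataclasses.replace(spec, center_z=4.0), grid, params)
    cons = ConstraintSet.from_field(phiA, params)
    return phiA, phiB, cons


def _fake_path(energies, params):
    """A StringPath whose images are unused: only energies matter."""
    n = len(energies)
    grid_dummy = None
    path = StringPath.__new__(StringPath)
    path.images = [None] * n
    path.alpha = np.linspace(0, 1, n)
    path.params = params
    path.cons = None
    path.energies = [
        EnergyBreakdown(EB=e, EG=0.0, A=1.0, V=1.0, k=params.k)
        for e in energies
    ]
    path.residuals = []
    path.converged = True
    return path


def test_analyze_path_simple_saddle(params):
    ana = analyze_path(_fake_path([0.0, 1.0, 0.0], params))
    assert ana.saddle_indices == [1]
    assert ana.minima_indices == [0, 2]
    assert ana.barriers["forward"] == pytest.approx(1.0)
    assert ana.barriers["backward"] == pytest.approx(1.0)


def test_analyze_path_metastable_intermediate(params):
    ana = analyze_path(_fake_path([0.0, 2.0, 1.0, 3.0, 0.0], params))
    assert ana.minima_indices == [0, 2, 4]
    assert ana.saddle_indices == [1, 3]
    assert ana.barriers["forward"] == pytest.approx(3.0)
    assert ana.barriers["escape_2_forward"] == pytest.approx(2.0)
    assert ana.barriers["escape_2_backward"] == pytest.approx(1.0)


def test_analyze_path_rejects_short(params):
    with pytest.raises(ValueError):
        analyze_path(_fake_path([0.0, 1.0], params))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.integers(0, 8), min_size=3, max_size=14))
def test_analyze_path_against_exhaustive_scan(values):
    """Strict interior extrema of a random profile match a brute scan, and
    every reported barrier is non-negative."""
    from memphase import ElasticParams

    params = ElasticParams(k=20.0, kG=-20.0)
    E = np.array(values, dtype=float)
    # perturb to break exact ties (analysis uses strict comparisons)
    E = E + 1e-9 * np.arange(len(E))
    ana = analyze_path(_fake_path(list(E), params))
    brute_minima = [i for i in range(1, len(E) - 1)
                    if E[i] < E[i - 1] and E[i] < E[i + 1]]
    brute_saddles = [i for i in range(1, len(E) - 1)
                     if E[i] > E[i - 1] and E[i] > E[i + 1]]
    assert [i for i in ana.minima_indices if 0 < i < len(E) - 1] == brute_minima
    assert ana.saddle_indices == brute_saddles
    assert all(v >= -1e-12 for v in ana.barriers.values())


def test_init_path_endpoints_and_trivial_cases(params, sphere_endpoints):
    phiA, phiB, cons = sphere_endpoints
    path = init_path(phiA, phiA, 5, params, dataclasses.replace(cons),
                     presmooth_iters=0)
    for im in path.images:
        assert np.array_equal(im.values, phiA.values)

    two = init_path(phiA, phiB, 2, params, dataclasses.replace(cons),
                    presmooth_iters=0)
    assert two.n_images == 2
    assert np.array_equal(two.images[0].values, phiA.values)
    assert np.array_equal(two.images[1].values, phiB.values)

    with pytest.raises(ValueError, match="violates"):
        bad = ConstraintSet(A0=cons.A0 * 3.0, V0=cons.V0)
        init_path(phiA, phiB, 4, params, bad)


def test_init_path_interior_images_satisfy_constraints(params,
                                                       sphere_endpoints):
    phiA, phiB, cons = sphere_endpoints
    from memphase import area_functional, volume_functional

    path = init_path(phiA, phiB, 7, params, dataclasses.replace(cons),
                     project=True)
    for im in path.images[1:-1]:
        assert abs(area_functional(im, params) - cons.A0) / cons.A0 < 5e-3
        assert abs(volume_functional(im) - cons.V0) / cons.V0 < 5e-3


def _seglens(p):
    w = get_operators(p.grid).weights
    f = [im.values.ravel() for im in p.images]
    return np.array([
        math.sqrt(float(w @ (f[i + 1] - f[i]) ** 2))
        for i in range(len(f) - 1)
    ])


def test_reparametrize_equalizes_spacing(params, sphere_endpoints):
    phiA, phiB, cons = sphere_endpoints
    path = init_path(phiA, phiB, 9, params, dataclasses.replace(cons),
                     presmooth_iters=0, interpolation="linear")
    # make spacing uneven on purpose by dropping interior images
    uneven = dataclasses.replace(
        path,
        images=[path.images[i] for i in (0, 1, 2, 3, 6, 7, 8)],
        alpha=path.alpha[[0, 1, 2, 3, 6, 7, 8]],
    )
    eq = reparametrize(uneven)
    lens = _seglens(eq)
    assert lens.max() / lens.min() <= 1.01
    # endpoints bit-identical
    assert np.array_equal(eq.images[0].values, phiA.values)
    assert np.array_equal(eq.images[-1].values, phiB.values)


def test_reparametrize_idempotent_on_equispaced_path(params, sphere_endpoints):
    """A straight line in field space with uniform parameter IS exactly
    equispaced; reparametrization must leave it untouched."""
    phiA, phiB, cons = sphere_endpoints
    a, b = phiA.values, phiB.values
    images = [ScalarField(phiA.grid, (1 - t) * a + t * b)
              for t in np.linspace(0.0, 1.0, 7)]
    path = StringPath(images=images, alpha=np.linspace(0, 1, 7),
                      params=params, cons=cons)
    again = reparametrize(path)
    for x, y in zip(path.images, again.images):
        assert np.abs(x.values - y.values).max() < 1e-10


def test_translation_path_is_energetically_neutral(params):
    """Rigid translation of an isolated vesicle is an energy plateau (the
    MEP between displaced copies), so the explicitly constructed
    translation path is flat within 0.1% of 8πk, stays quantized at genus
    0, and is (near) a fixed point of the string iteration."""
    spec = ShapeSpec(kind="sphere", radius=10.0, center_z=-4.0)
    grid = make_grid_for_shape(spec, params, clearance=12.0, spacing=2.0 / 3.0)
    phi0 = make_shape(spec, grid, params)
    cons = ConstraintSet.from_field(phi0, params)
    star = relax(phi0, params, dataclasses.replace(cons)).phi_star
    # exact grid translations of one relaxed vesicle: all images share the
    # same discrete energy, so the path IS the (neutral) MEP
    n_shift = int(round(8.0 / grid.spacing))
    shifts = np.linspace(0, n_shift, 7).round().astype(int)
    images = [ScalarField(grid, np.roll(star.values, s, axis=1))
              for s in shifts]
    cons = ConstraintSet.from_field(images[0], params)
    path = StringPath(images=images, alpha=np.linspace(0, 1, len(images)),
                      params=params, cons=cons)
    scale = 8.0 * math.pi * params.k

    relaxed = run_string(path, StringOptions(max_cycles=10, inner_iters=4,
                                             min_cycles=2))
    E = relaxed.energy_array()
    assert np.abs(E - E[0]).max() < 1e-3 * scale
    # the Gaussian energy is constant along the plateau and identifies
    # genus 0 on every image (this vesicle is small, λ = 0.05, so the
    # quantization residual is finite but uniform)
    from memphase import genus_from_gaussian

    quant = np.array([bd.EG for bd in relaxed.energies]) / (4 * math.pi * params.kG)
    assert np.ptp(quant) < 1e-3
    for bd in relaxed.energies:
        assert genus_from_gaussian(bd.EG, params.kG)[0] == 0
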