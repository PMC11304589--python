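"""Programmatic phase-field fixtures and level-set diagnostics.

Initial conditions are built from signed-distance functions d(x) (positive
inside the vesicle) through the equilibrium profile ϕ = tanh(d/(√2ϵ)).
Available shapes: sphere, two spheres, oblate spheroid (aspect ratio
solvable for a target reduced volume) and the Clifford torus
(tube-center/tube radius ratio √2, reduced volume ≈ 0.71).

The ϕ = tanh(±3/2) isolines mark the beginning and end of the diffuse
interface; for a tanh profile they sit at signed distances ∓(3/√2)ϵ from
the mid-surface.  ``membrane_separation`` measures the gap between the
outer isolines of two approaching membranes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from skimage import measure

from .energetics import ElasticParams
from .grid import AxisymGrid, ScalarField

__all__ = [
    "ShapeSpec",
    "tanh_from_distance",
    "make_shape",
    "make_grid_for_shape",
    "interface_band",
    "membrane_separation",
    "oblate_aspect_for_reduced_volume",
    "spheroid_area_volume",
]

SQRT2 = math.sqrt(2.0)

ShapeKind = Literal["sphere", "two_spheres", "ellipsoid", "clifford_torus"]

#: half-width of the diffuse interface band, in units of ϵ
BAND_HALF_WIDTH = 3.0 / SQRT2


@dataclass
class ShapeSpec:
    """Geometric specification of an initial phase-field configuration.

    For ``ellipsoid`` the aspect ratio can be solved from a target reduced
    volume ``v`` at fixed area (Dve); for ``clifford_torus`` the radii ratio
    is fixed at √2.  ``radius`` is the sphere radius, the equatorial
    semi-axis of the spheroid, or the tube radius of the torus; ``gap`` is
    the surface-to-surface distance of the two-sphere fixture.
    """

    kind: ShapeKind
    radius: float = 0.0
    aspect: float = 1.0  # c/a of the spheroid (c along the symmetry axis)
    gap: float = 0.0
    center_z: float = 0.0
    v: float | None = None
    Dve: float | None = None


def tanh_from_distance(d: ScalarField, params: ElasticParams) -> ScalarField:
    """Equilibrium profile ϕ = tanh(d/(√2ϵ)) from a signed distance field."""
    return ScalarField(d.grid, np.tanh(d.values / (SQRT2 * params.eps)))


# ---------------------------------------------------------------------------
# geometry helpers


def spheroid_area_volume(a: float, c: float) -> tuple[float, float]:
    """Surface area and volume of a spheroid with semi-axes (a, a, c)."""
    V = 4.0 / 3.0 * math.pi * a * a * c
    if abs(c - a) < 1e-12 * a:
        return 4.0 * math.pi * a * a, V
    if c < a:  # oblate
        e = math.sqrt(1.0 - (c / a) ** 2)
        A = 2.0 * math.pi * a * a * (1.0 + (1.0 - e * e) / e * math.atanh(e))
    else:  # prolate
        e = math.sqrt(1.0 - (a / c) ** 2)
        A = 2.0 * math.pi * a * a * (1.0 + c / (a * e) * math.asin(e))
    return A, V


def reduced_volume_spheroid(x: float) -> float:
    """Reduced volume of a spheroid as a function of aspect ratio x = c/a."""
    A, V = spheroid_area_volume(1.0, x)
    dve = math.sqrt(A / math.pi)
    return V / (math.pi * dve**3 / 6.0)


def oblate_aspect_for_reduced_volume(v: float) -> float:
    """Aspect ratio c/a < 1 of the oblate spheroid with reduced volume v."""
    if not 0.0 < v < 1.0:
        raise ValueError("reduced volume must lie in (0, 1)")
    return brentq(lambda x: reduced_volume_spheroid(x) - v, 1e-4, 1.0 - 1e-9)


def prolate_aspect_for_reduced_volume(v: float) -> float:
    """Aspect ratio c/a > 1 of the prolate spheroid with reduced volume v.

    Useful to seed dumbbell-like single-vesicle states at low reduced
    volume without risking a topology change during relaxation."""
    if not 0.0 < v < 1.0:
        raise ValueError("reduced volume must lie in (0, 1)")
    return brentq(lambda x: reduced_volume_spheroid(x) - v, 1.0 + 1e-9, 80.0)


def _sd_sphere(R: np.ndarray, Z: np.ndarray, radius: float, z0: float) -> np.ndarray:
    return radius - np.sqrt(R**2 + (Z - z0) ** 2)


def _sd_torus(R: np.ndarray, Z: np.ndarray, ring: float, tube: float,
              z0: float) -> np.ndarray:
    return tube - np.sqrt((R - ring) ** 2 + (Z - z0) ** 2)


def _sd_ellipse(R: np.ndarray, Z: np.ndarray, a: float, c: float,
                z0: float) -> np.ndarray:
    """Signed distance to the spheroid r²/a² + z²/c² = 1 (positive inside).

    Exact point-to-ellipse distance in the (r, z) half-plane via Newton
    iteration on the ellipse parameter.
    """
    r = np.abs(R).ravel()
    z = np.abs(Z - z0).ravel()
    t = np.arctan2(z * a, r * c)  # initial parameter guess
    for _ in range(40):
        ct, st = np.cos(t), np.sin(t)
        # minimize (a ct - r)^2 + (c st - z)^2 over t
        f = (a * a - c * c) * ct * st - r * a * st + z * c * ct
        fp = (a * a - c * c) * (ct * ct - st * st) - r * a * ct - z * c * st
        step = f / np.where(np.abs(fp) > 1e-30, fp, 1e-30)
        step = np.clip(step, -0.3, 0.3)
        t = np.clip(t - step, 0.0, math.pi / 2.0)
    dist = np.sqrt((a * np.cos(t) - r) ** 2 + (c * np.sin(t) - z) ** 2)
    inside = (r / a) ** 2 + (z / c) ** 2 <= 1.0
    return np.where(inside, dist, -dist).reshape(R.shape)


#: Clifford ratio of tube-center circle radius to tube radius
CLIFFORD_RATIO = SQRT2


def _solve_geometry(spec: ShapeSpec) -> ShapeSpec:
    """Resolve optional (v, Dve) targets into concrete radii."""
    spec = ShapeSpec(**vars(spec))
    if spec.kind == "ellipsoid" and spec.v is not None:
        spec.aspect = oblate_aspect_for_reduced_volume(spec.v)
    if spec.Dve is not None:
        if spec.kind == "sphere":
            spec.radius = spec.Dve / 2.0
        elif spec.kind == "ellipsoid":
            A_unit, _ = spheroid_area_volume(1.0, spec.aspect)
            spec.radius = spec.Dve * math.sqrt(math.pi / A_unit)
        elif spec.kind == "clifford_torus":
            # A = 4π² ring·tube = 4π²√2 tube²;  Dve = √(A/π)
            spec.radius = spec.Dve / math.sqrt(4.0 * math.pi * CLIFFORD_RATIO)
        elif spec.kind == "two_spheres":
            # two equal spheres: A = 8πR²
            spec.radius = spec.Dve / (2.0 * SQRT2)
    if spec.radius <= 0:
        raise ValueError("shape radius could not be resolved; give radius or Dve")
    return spec


def shape_extents(spec: ShapeSpec) -> tuple[float, float]:
    """(max radial extent, max |z| extent) of the resolved shape."""
    spec = _solve_geometry(spec)
    if spec.kind == "sphere":
        return spec.radius, spec.radius + abs(spec.center_z)
    if spec.kind == "ellipsoid":
        return spec.radius, spec.radius * spec.aspect + abs(spec.center_z)
    if spec.kind == "clifford_torus":
        return spec.radius * (1.0 + CLIFFORD_RATIO), spec.radius + abs(spec.center_z)
    if spec.kind == "two_spheres":
        return spec.radius, 2.0 * spec.radius + spec.gap / 2.0 + abs(spec.center_z)
    raise ValueError(f"unknown shape kind {spec.kind!r}")


def make_grid_for_shape(
    spec: ShapeSpec, params: ElasticParams, clearance: float = 8.0,
    spacing: float | None = None,
) -> AxisymGrid:
    """Grid that contains the shape with ``clearance``·ϵ margin to all walls."""
    e = params.eps
    h = spacing if spacing is not None else 2.0 * e / 3.0
    r_ext, z_ext = shape_extents(spec)
    return AxisymGrid.from_extents(
        r_max=r_ext + clearance * e, z_min=-(z_ext + clearance * e),
        z_max=z_ext + clearance * e, spacing=h,
    )


def make_shape(spec: ShapeSpec, grid: AxisymGrid, params: ElasticParams) -> ScalarField:
    """Build the tanh phase field of the requested shape on ``grid``."""
    spec = _solve_geometry(spec)
    e = params.eps
    if any(rad <= 3.0 * e for rad in _min_radii(spec)):
        raise ValueError("all shape radii must exceed 3ϵ to fit the interface")
    r_ext, z_ext = shape_extents(spec)
    if (r_ext > grid.r_max - 6.0 * e or z_ext > grid.z_max - 6.0 * e
            or -z_ext < grid.z_min + 6.0 * e):
        raise ValueError(
            f"shape (extents r={r_ext:.3g}, |z|={z_ext:.3g}) needs at least "
            f"6ϵ clearance; enlarge the domain to r_max>{r_ext + 6 * e:.3g}, "
            f"|z|>{z_ext + 6 * e:.3g}"
        )
    R, Z = grid.meshgrid()
    if spec.kind == "sphere":
        d = _sd_sphere(R, Z, spec.radius, spec.center_z)
    elif spec.kind == "two_spheres":
        dz = spec.radius + spec.gap / 2.0
        d1 = _sd_sphere(R, Z, spec.radius, spec.center_z + dz)
        d2 = _sd_sphere(R, Z, spec.radius, spec.center_z - dz)
        d = np.maximum(d1, d2)  # union of the two interiors
    elif spec.kind == "ellipsoid":
        d = _sd_ellipse(R, Z, spec.radius, spec.radius * spec.aspect, spec.center_z)
    elif spec.kind == "clifford_torus":
        d = _sd_torus(R, Z, spec.radius * CLIFFORD_RATIO, spec.radius, spec.center_z)
    else:
        raise ValueError(f"unknown shape kind {spec.kind!r}")
    return tanh_from_distance(ScalarField(grid, d), params)


def _min_radii(spec: ShapeSpec) -> list[float]:
    if spec.kind == "ellipsoid":
        return [spec.radius, spec.radius * spec.aspect]
    return [spec.radius]


# ---------------------------------------------------------------------------
# level-set diagnostics


def _contours_at(phi: ScalarField, level: float) -> list[np.ndarray]:
    """Isolines of ϕ at ``level`` as arrays of (r, z) points."""
    grid = phi.grid
    h = grid.spacing
    out = []
    for c in measure.find_contours(phi.values, level):
        rz = np.empty_like(c)
        rz[:, 0] = c[:, 0] * h  # row index -> r
        rz[:, 1] = grid.z_min + c[:, 1] * h
        out.append(rz)
    return out


def interface_band(phi: ScalarField, params: ElasticParams) -> tuple[
        list[np.ndarray], list[np.ndarray]]:
    """The ϕ = tanh(−3/2) and ϕ = tanh(+3/2) isolines bounding the membrane.

    Returns ``(outer, inner)`` lists of polylines in (r, z) coordinates; for
    a tanh profile they sit at distances ±(3/√2)ϵ ≈ 2.12ϵ from ϕ = 0.
    Empty lists mean the level set does not occur on the grid.
    """
    lo = math.tanh(-1.5)
    hi = math.tanh(1.5)
    return _contours_at(phi, lo), _contours_at(phi, hi)


def membrane_separation(phi: ScalarField, params: ElasticParams) -> float:
    """Minimal gap between the outer ends of two distinct membrane interfaces.

    Finds the disjoint components of the ϕ = tanh(−3/2) isoline and returns
    the smallest pairwise point distance between distinct components, i.e.
    the water gap between two approaching membranes.  Raises ``ValueError``
    if fewer than two components exist (single vesicle or no interface).
    """
    comps = _contours_at(phi, math.tanh(-1.5))
    if len(comps) < 2:
        raise ValueError(
            "membrane separation undefined: fewer than two interface "
            f"components found ({len(comps)})"
        )
    best = math.inf
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            d2 = np.min(
                np.sum(
                    (comps[i][:, None, :] - comps[j][None, :, :]) ** 2, axis=-1
                )
            )
            best = min(best, math.sqrt(d2))
    return best
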