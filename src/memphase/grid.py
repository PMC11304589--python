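"""Axisymmetric (r-z) structured grid, finite-difference operators and
cylindrical volume integration.

All field computations in the package run on a uniform grid in the r-z
half-plane, r >= 0 being the distance from the symmetry axis.  Scalar
fields are stored as ``(nr, nz)`` arrays; the flattened ordering is
row-major with the radial index first, which is what the sparse operator
matrices act on.

The cylindrical Laplacian is ∂²/∂r² + (1/r)∂/∂r + ∂²/∂z².  On the axis the
1/r term is regularized with the standard even-symmetry formula
``lap f |_{r=0} = 4 (f(dr) - f(0)) / dr² + ∂²f/∂z²``.  Volume integrals
carry the 2πr weight; the axis node receives the exact cell integral
π dr²/4 so that fields constant in r integrate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AxisymGrid",
    "ScalarField",
    "VectorField",
    "laplacian",
    "gradient",
    "integrate",
]

_REL_TOL = 1e-12


@dataclass(frozen=True)
class AxisymGrid:
    """Uniform axisymmetric grid on [0, r_max] x [z_min, z_max].

    The spacing must be identical in r and z (within 1e-12 relative);
    ``nr`` and ``nz`` are node counts, so ``spacing = r_max/(nr-1)``.
    """

    r_max: float
    z_min: float
    z_max: float
    nr: int
    nz: int

    r_min: float = 0.0

    def __post_init__(self) -> None:
        if self.r_min != 0.0:
            raise ValueError("r_min must be 0 (the symmetry axis)")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")
        if self.nr < 8 or self.nz < 8:
            raise ValueError("grid too small: nr and nz must be >= 8")
        hr = self.r_max / (self.nr - 1)
        hz = (self.z_max - self.z_min) / (self.nz - 1)
        if abs(hr - hz) > _REL_TOL * max(abs(hr), abs(hz)):
            raise ValueError(
                f"anisotropic spacing: dr={hr!r} != dz={hz!r}; "
                "use node counts giving equal spacing in r and z"
            )

    @property
    def spacing(self) -> float:
        return self.r_max / (self.nr - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nr, self.nz)

    @property
    def size(self) -> int:
        return self.nr * self.nz

    @cached_property
    def r(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.nr)

    @cached_property
    def z(self) -> np.ndarray:
        return np.linspace(self.z_min, self.z_max, self.nz)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return broadcastable (R, Z) coordinate arrays of shape (nr, nz)."""
        return np.meshgrid(self.r, self.z, indexing="ij")

    @classmethod
    def from_extents(
        cls, r_max: float, z_min: float, z_max: float, spacing: float
    ) -> "AxisymGrid":
        """Build a grid with (approximately) the requested spacing.

        Extents are stretched by less than one cell so that the spacing is
        uniform and identical in both directions.
        """
        nr = int(round(r_max / spacing)) + 1
        h = r_max / (nr - 1)
        nz = int(round((z_max - z_min) / h))
        zc = 0.5 * (z_min + z_max)
        half = 0.5 * nz * h
        return cls(r_max=r_max, z_min=zc - half, z_max=zc + half, nr=nr, nz=nz + 1)


def _check_values(grid: AxisymGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"{name} has shape {values.shape}, expected {grid.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains NaN or Inf")
    return values


@dataclass
class ScalarField:
    """A scalar field sampled on an :class:`AxisymGrid`."""

    grid: AxisymGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "values")

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())


@dataclass
class VectorField:
    """An axisymmetric vector field with radial and axial components."""

    grid: AxisymGrid
    vr: np.ndarray
    vz: np.ndarray

    def __post_init__(self) -> None:
        self.vr = _check_values(self.grid, self.vr, "vr")
        self.vz = _check_values(self.grid, self.vz, "vz")


# ---------------------------------------------------------------------------
# sparse operator assembly (cached per grid)


def _d1_matrix(n: int, h: float) -> sp.csr_matrix:
    """Second-order first derivative: centered interior, one-sided edges."""
    D = sp.lil_matrix((n, n))
    inv = 1.0 / (2.0 * h)
    for i in range(1, n - 1):
        D[i, i - 1] = -inv
        D[i, i + 1] = inv
    D[0, 0], D[0, 1], D[0, 2] = -3 * inv, 4 * inv, -inv
    D[n - 1, n - 3], D[n - 1, n - 2], D[n - 1, n - 1] = inv, -4 * inv, 3 * inv
    return D.tocsr()


def _d2_matrix(n: int, h: float) -> sp.csr_matrix:
    """Second derivative: centered interior, one-sided second-order edges."""
    D = sp.lil_matrix((n, n))
    inv = 1.0 / (h * h)
    for i in range(1, n - 1):
        D[i, i - 1] = inv
        D[i, i] = -2 * inv
        D[i, i + 1] = inv
    D[0, :4] = np.array([2.0, -5.0, 4.0, -1.0]) * inv
    D[n - 1, n - 4:] = np.array([-1.0, 4.0, -5.0, 2.0]) * inv
    return D.tocsr()


class GridOperators:
    """Sparse differential operators and quadrature weights for one grid.

    Attributes
    ----------
    Gr, Gz : csr_matrix
        First-derivative operators (r-component zero on the axis).
    Lap : csr_matrix
        Cylindrical Laplacian with the regularized axis row.
    weights : ndarray, shape (nr*nz,)
        Quadrature weights including the 2πr metric factor; ``w @ f`` is the
        volume integral of the flattened field f.
    """

    def __init__(self, grid: AxisymGrid) -> None:
        nr, nz = grid.nr, grid.nz
        h = grid.spacing
        r = grid.r

        D1r = _d1_matrix(nr, h)
        D1z = _d1_matrix(nz, h)
        D2r = _d2_matrix(nr, h)
        D2z = _d2_matrix(nz, h)
        Ir = sp.identity(nr, format="csr")
        Iz = sp.identity(nz, format="csr")

        # gradient: radial component vanishes on the axis for even fields
        D1r_grad = D1r.tolil()
        D1r_grad[0, :] = 0.0
        self.Gr = sp.kron(D1r_grad.tocsr(), Iz, format="csr")
        self.Gz = sp.kron(Ir, D1z, format="csr")

        # radial part of the Laplacian: D2 + (1/r) D1, axis row regularized
        inv_r = np.zeros(nr)
        inv_r[1:] = 1.0 / r[1:]
        Rad = (D2r + sp.diags(inv_r) @ D1r).tolil()
        Rad[0, :] = 0.0
        Rad[0, 0] = -4.0 / h**2
        Rad[0, 1] = 4.0 / h**2
        self.Lap = (sp.kron(Rad.tocsr(), Iz) + sp.kron(Ir, D2z)).tocsr()

        # quadrature: exact cell integrals of 2πr in r, trapezoid in z
        wr = 2.0 * np.pi * r * h
        wr[0] = np.pi * (h / 2.0) ** 2
        wr[-1] = np.pi * h * (r[-1] - h / 4.0)
        wz = np.full(nz, h)
        wz[0] = wz[-1] = h / 2.0
        self.weights = np.outer(wr, wz).ravel()
        self.grid = grid

        self.GrT = self.Gr.T.tocsr()
        self.GzT = self.Gz.T.tocsr()
        self.LapT = self.Lap.T.tocsr()


_OPS_CACHE: dict[AxisymGrid, GridOperators] = {}


def get_operators(grid: AxisymGrid) -> GridOperators:
    ops = _OPS_CACHE.get(grid)
    if ops is None:
        ops = GridOperators(grid)
        if len(_OPS_CACHE) > 32:  # keep the cache bounded
            _OPS_CACHE.clear()
        _OPS_CACHE[grid] = ops
    return ops


# ---------------------------------------------------------------------------
# public operator API on fields


def laplacian(field: ScalarField) -> ScalarField:
    """Cylindrical Laplacian of a scalar field (second-order stencil)."""
    ops = get_operators(field.grid)
    out = ops.Lap @ field.values.ravel()
    return ScalarField(field.grid, out.reshape(field.grid.shape))


def gradient(field: ScalarField) -> VectorField:
    """Gradient (∂/∂r, ∂/∂z); the r-component is zero on the axis."""
    ops = get_operators(field.grid)
    flat = field.values.ravel()
    vr = (ops.Gr @ flat).reshape(field.grid.shape)
    vz = (ops.Gz @ flat).reshape(field.grid.shape)
    return VectorField(field.grid, vr, vz)


def integrate(field: ScalarField) -> float:
    """Volume integral ∫ f · 2πr dr dz over the computational domain."""
    ops = get_operators(field.grid)
    return float(ops.weights @ field.values.ravel())
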