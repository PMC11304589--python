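"""Constrained minimization of the membrane free energy.

A vesicle's area is fixed by the large tension cost of stretching, and its
enclosed volume by osmotic conditions, so the physically relevant minima
of E[ϕ] are at prescribed A[ϕ] = A0 and V[ϕ] = V0.  The constraints are
imposed with an augmented Lagrangian

    L(ϕ; μ) = E[ϕ] + μ_A ĉ_A + μ_V ĉ_V + (p/2)(ĉ_A² + ĉ_V²),

with relative violations ĉ_A = (A−A0)/A0, ĉ_V = (V−V0)/V0, first-order
multiplier updates μ ← μ + p ĉ, and penalty doubling whenever a violation
fails to halve between outer iterations.

Inner solver.  The plain L² gradient flow of this functional is extremely
stiff: interface-profile modes relax on the ϵ⁴-scale while shape modes
relax on the Dve⁴-scale, so an explicit (or even linearly implicit)
integrator needs a prohibitive number of steps at vesicle-scale problems.
Instead each inner stage minimizes L directly with L-BFGS in a
preconditioned variable u = √(2c_EB) √W (w′(ϕ) + σ − ∇²) ϕ, where
w′(ϕ) = (3ϕ²−1)/ϵ² is the linearization of the double-well reaction and W
the quadrature weights.  Since the bending Hessian is approximately
2c_EB (∇² − w′)ᵀ W (∇² − w′), this change of variables equalizes the
interface and shape mode curvatures (the small shift σ keeps the operator
invertible); the sparse LU factorization is refreshed at every outer
iteration.  ``augmented_step``, a single explicit gradient-flow step with
its dt ∝ h⁴ stability bound, is kept as a reference kernel.

Boundary conditions are Dirichlet ϕ = −1 on the outer walls (vesicle
exterior); the axis needs no condition beyond the operator symmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu

from .energetics import (
    ElasticParams,
    EnergyBreakdown,
    _prefactors,
    area_functional,
    bending_energy,
    energy_breakdown,
    energy_operators,
    gaussian_energy,
    grad_area,
    grad_bending,
    grad_gaussian,
    grad_volume,
    volume_functional,
)
from .grid import AxisymGrid, ScalarField, get_operators

__all__ = [
    "ConstraintSet",
    "RelaxOptions",
    "RelaxResult",
    "relax",
    "augmented_step",
    "stability_bound",
]


@dataclass
class ConstraintSet:
    """Area/volume targets, multipliers and penalty of the augmented
    Lagrangian."""

    A0: float
    V0: float
    mult_A: float = 0.0
    mult_V: float = 0.0
    penalty: float = 0.0  # 0 -> chosen automatically from 8πk
    tol_A: float = 1e-3
    tol_V: float = 1e-3

    def __post_init__(self) -> None:
        if self.A0 <= 0 or self.V0 <= 0:
            raise ValueError("constraint targets A0, V0 must be positive")
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        for tol in (self.tol_A, self.tol_V):
            if not 0.0 < tol < 1.0:
                raise ValueError("constraint tolerances must lie in (0, 1)")

    @classmethod
    def from_field(cls, phi: ScalarField, params: ElasticParams,
                   **kwargs) -> "ConstraintSet":
        """Targets taken from the area and volume of an existing field."""
        return cls(A0=area_functional(phi, params),
                   V0=volume_functional(phi), **kwargs)


@dataclass
class RelaxOptions:
    """Solver options for :func:`relax`.

    ``tol_res`` is the sup-norm of the constraint-projected variational
    derivative δL/δϕ in units of 8πk/ϵ³; ``precond_shift`` is the σ of the
    preconditioner in units of 1/ϵ².
    """

    max_outer: int = 40
    inner_maxiter: int = 200
    tol_res: float = 1e-4
    precond_shift: float = 1e-3
    penalty_growth: float = 2.0
    lbfgs_memory: int = 20
    sanity_bound: float = 1.5
    verbose: bool = False


@dataclass
class RelaxResult:
    phi_star: ScalarField
    breakdown: EnergyBreakdown
    iterations: int
    residual: float
    constraint_violation: tuple[float, float]
    converged: bool
    cons: ConstraintSet
    history: list[dict] = field(default_factory=list)


class _Workspace:
    """Interior-node bookkeeping and preconditioner for one grid."""

    def __init__(self, grid: AxisymGrid, params: ElasticParams,
                 shift: float) -> None:
        self.grid = grid
        self.params = params
        self.eops = energy_operators(grid)
        self.gops = get_operators(grid)
        nr, nz = grid.shape
        mask = np.ones((nr, nz), dtype=bool)
        mask[-1, :] = False  # r = r_max wall
        mask[:, 0] = False   # z = z_min wall
        mask[:, -1] = False  # z = z_max wall
        self.mask = mask.ravel()
        self.idx = np.flatnonzero(self.mask)
        self.w_int = self.eops.weights[self.idx]
        c_b, _, _ = _prefactors(params)
        self.scale = math.sqrt(2.0 * c_b)
        self.sqrt_w = np.sqrt(self.w_int)
        self.sigma = shift / params.eps**2
        self._lap_int = self.gops.Lap[self.idx][:, self.idx].tocsc()
        self.lu = None

    def refresh(self, phi_full: np.ndarray) -> None:
        """Refactorize M = w′(ϕ) + σ − ∇² at the current state."""
        e = self.params.eps
        wprime = (3.0 * phi_full[self.idx] ** 2 - 1.0) / e**2
        M = sp.diags(wprime + self.sigma) - self._lap_int
        self.M = M.tocsc()
        self.MT = self.M.T.tocsc()
        self.lu = splu(self.M)
        self.luT = splu(self.MT)

    def to_u(self, phi_int: np.ndarray) -> np.ndarray:
        return self.scale * self.sqrt_w * (self.M @ phi_int)

    def to_phi(self, u: np.ndarray) -> np.ndarray:
        return self.lu.solve(u / (self.scale * self.sqrt_w))

    def grad_to_u(self, g_int: np.ndarray) -> np.ndarray:
        return self.luT.solve(g_int) / (self.scale * self.sqrt_w)


def _al_value_grad(phi_full, ws, params, cons):
    """Augmented-Lagrangian value and full nodal gradient."""
    eops = ws.eops
    f = ScalarField(ws.grid, phi_full.reshape(ws.grid.shape))
    E = bending_energy(f, params) + gaussian_energy(f, params)
    A = area_functional(f, params)
    V = volume_functional(f)
    cA = (A - cons.A0) / cons.A0
    cV = (V - cons.V0) / cons.V0
    p = cons.penalty
    val = (E + cons.mult_A * cA + cons.mult_V * cV
           + 0.5 * p * (cA * cA + cV * cV))
    g = grad_bending(phi_full, eops, params) + grad_gaussian(phi_full, eops, params)
    g += (cons.mult_A + p * cA) / cons.A0 * grad_area(phi_full, eops, params)
    g += (cons.mult_V + p * cV) / cons.V0 * grad_volume(phi_full, eops)
    return val, g, (E, A, V, cA, cV)


def _projected_residual(g_nodal, gA, gV, ws, params):
    """Sup-norm of δL/δϕ with the constraint directions projected out,
    in units of 8πk/ϵ³."""
    w = ws.w_int
    d = g_nodal[ws.idx] / w
    basis = []
    for gc in (gA[ws.idx] / w, gV[ws.idx] / w):
        v = gc.copy()
        for b in basis:
            v -= (w * b @ v) / (w * b @ b) * b
        nrm = math.sqrt(float(w * v @ v))
        if nrm > 0:
            basis.append(v / nrm)
    for b in basis:
        d = d - float(w * b @ d) * b
    return float(np.max(np.abs(d))) * params.eps**3 / (8.0 * math.pi * params.k)


def relax(
    phi0: ScalarField,
    params: ElasticParams,
    cons: ConstraintSet,
    opts: RelaxOptions | None = None,
) -> RelaxResult:
    """Find a local minimizer of E[ϕ] at fixed area and volume.

    Returns a :class:`RelaxResult`; ``converged`` is True when both
    constraint violations are inside their tolerances and the projected
    residual is below ``opts.tol_res``.  Divergence (NaN energy or ϕ
    leaving the sanity bound) raises ``FloatingPointError`` carrying the
    last valid state in ``args``.
    """
    opts = opts or RelaxOptions()
    if cons.penalty == 0.0:
        cons.penalty = 200.0 * 8.0 * math.pi * params.k
    ws = _Workspace(phi0.grid, params, opts.precond_shift)
    phi = phi0.values.ravel().copy()
    phi[~ws.mask] = -1.0

    history: list[dict] = []
    prev_viol = np.inf
    total_inner = 0
    residual = np.inf
    converged = False

    for outer in range(opts.max_outer):
        ws.refresh(phi)
        u0 = ws.to_u(phi[ws.idx])
        state = {}

        def objective(u):
            phi_int = ws.to_phi(u)
            full = phi.copy()
            full[ws.idx] = phi_int
            val, g, extras = _al_value_grad(full, ws, params, cons)
            if not np.isfinite(val):
                raise FloatingPointError("energy diverged during relaxation",
                                         ScalarField(ws.grid,
                                                     phi.reshape(ws.grid.shape)))
            state["full"] = full
            state["g"] = g
            state["extras"] = extras
            return val, ws.grad_to_u(g[ws.idx])

        res = minimize(objective, u0, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=opts.inner_maxiter,
                                    maxcor=opts.lbfgs_memory,
                                    ftol=1e-14, gtol=1e-12))
        phi[ws.idx] = ws.to_phi(res.x)
        if np.max(np.abs(phi)) > opts.sanity_bound:
            raise FloatingPointError(
                "phase field left the sanity bound |phi| <= "
                f"{opts.sanity_bound}",
                ScalarField(ws.grid, phi.reshape(ws.grid.shape)))
        total_inner += res.nit
        E, A, V, cA, cV = state["extras"]

        gA = grad_area(phi, ws.eops, params)
        gV = grad_volume(phi, ws.eops)
        residual = _projected_residual(state["g"], gA, gV, ws, params)
        history.append(dict(outer=outer, E=E, A=A, V=V, cA=cA, cV=cV,
                            residual=residual, penalty=cons.penalty,
                            mult_A=cons.mult_A, mult_V=cons.mult_V,
                            inner_iters=res.nit))
        if opts.verbose:
            print(f"[relax {outer:2d}] E/8pik={E / (8 * math.pi * params.k):.5f} "
                  f"cA={cA:+.2e} cV={cV:+.2e} res={residual:.2e} "
                  f"nit={res.nit}")

        ok_cons = abs(cA) <= cons.tol_A and abs(cV) <= cons.tol_V
        if ok_cons and residual <= opts.tol_res:
            converged = True
            break

        # first-order multiplier update; stiffen penalty on stagnation
        cons.mult_A += cons.penalty * cA
        cons.mult_V += cons.penalty * cV
        viol = max(abs(cA), abs(cV))
        if viol > 0.5 * prev_viol and not ok_cons:
            cons.penalty *= opts.penalty_growth
        prev_viol = viol

    phi_star = ScalarField(phi0.grid, phi.reshape(phi0.grid.shape))
    bd = energy_breakdown(phi_star, params)
    return RelaxResult(
        phi_star=phi_star,
        breakdown=bd,
        iterations=total_inner,
        residual=residual,
        constraint_violation=(abs((bd.A - cons.A0) / cons.A0),
                              abs((bd.V - cons.V0) / cons.V0)),
        converged=converged,
        cons=cons,
        history=history,
    )


def stability_bound(grid: AxisymGrid, params: ElasticParams) -> float:
    """Largest stable explicit time step of the L² gradient flow.

    The stiffest term of δE/δϕ is the biharmonic piece 2c_EB ∇⁴ϕ with
    spectral radius ≈ 2c_EB (8/h²)², giving dt_max = h⁴/(64 c_EB).
    """
    c_b, _, _ = _prefactors(params)
    return grid.spacing**4 / (64.0 * c_b)


def augmented_step(
    phi: ScalarField,
    cons: ConstraintSet,
    params: ElasticParams,
    dt: float,
) -> ScalarField:
    """One explicit gradient-flow step on the augmented Lagrangian.

    Reference (and deliberately simple) inner kernel: descends along the
    continuum variational derivative δL/δϕ with a fixed time step.  ``dt``
    above the explicit stability bound is rejected with the computed bound
    in the error message.  Multiplier updates are the caller's
    responsibility (:func:`relax` applies them on its outer schedule).
    """
    bound = stability_bound(phi.grid, params)
    if dt > bound:
        raise ValueError(
            f"dt = {dt:g} exceeds the explicit stability bound {bound:g} "
            "for this grid and bending rigidity"
        )
    if cons.penalty == 0.0:
        cons.penalty = 200.0 * 8.0 * math.pi * params.k
    ws = _Workspace(phi.grid, params, shift=0.0)
    flat = phi.values.ravel().copy()
    flat[~ws.mask] = -1.0
    _, g, _ = _al_value_grad(flat, ws, params, cons)
    step = np.zeros_like(flat)
    step[ws.idx] = (g[ws.idx] / ws.w_int) * dt
    out = flat - step
    return ScalarField(phi.grid, out.reshape(phi.grid.shape))
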