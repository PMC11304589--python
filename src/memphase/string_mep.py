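"""Minimal energy paths between vesicle configurations: the string method.

A minimal energy path (MEP) between two metastable phase-field states is
a curve ϕ_α, α ∈ [0,1], everywhere tangent to the energy gradient except
at critical points.  It is computed with the simplified string method:
the path is discretized into N images which are alternately (i) relaxed a
few inner iterations toward lower constrained energy and (ii) redistributed
along the path so that consecutive images are equidistant in the L² norm
of the phase field (the 2πr-weighted norm of the underlying 3D field).
Fixed membrane area and enclosed volume are enforced on every image by
the same augmented-Lagrangian machinery used for single-state relaxation,
so all configurations along the path share one reduced volume.

The converged energy profile E(α) exposes the transition mechanics:
interior minima are metastable intermediates (hemifusion-like states),
interior maxima are saddle points whose heights set the forward/backward
barriers, and the Gaussian energy EG(α) jumps by 4πkG·Δ(1−g) across the
topological transition while staying quantized elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .energetics import (
    ElasticParams,
    EnergyBreakdown,
    energy_breakdown,
    grad_area,
    grad_volume,
)
from .grid import AxisymGrid, ScalarField
from .relax import ConstraintSet, RelaxOptions, _al_value_grad, _Workspace
from scipy.optimize import minimize

__all__ = [
    "StringPath",
    "StringOptions",
    "PathAnalysis",
    "init_path",
    "run_string",
    "reparametrize",
    "refine_segment",
    "analyze_path",
    "rescale_field",
    "rescale_path",
]


@dataclass
class StringPath:
    """An ordered sequence of phase-field images with path metadata.

    ``alpha`` is the normalized cumulative L² arc length (0 at the first
    image, 1 at the last); ``energies`` holds one breakdown per image once
    computed.  All images share the grid, the elastic parameters and the
    area/volume targets in ``cons``.
    """

    images: list[ScalarField]
    alpha: np.ndarray
    params: ElasticParams
    cons: ConstraintSet
    energies: list[EnergyBreakdown] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def grid(self) -> AxisymGrid:
        return self.images[0].grid

    @property
    def n_images(self) -> int:
        return len(self.images)

    def energy_array(self) -> np.ndarray:
        if not self.energies:
            raise ValueError("energies not attached; run run_string first")
        return np.array([bd.E for bd in self.energies])


@dataclass
class StringOptions:
    """Options for :func:`run_string`.

    ``spacing_spec`` is either None (uniform L² spacing) or a tuple
    ``(n_first, "min")`` placing ``n_first`` of the images uniformly
    between the start and the interior energy minimum and the rest after
    it (the split used for fusion paths with a hemifusion intermediate).
    Convergence is declared either when the largest per-cycle image
    displacement falls below ``tol_displacement`` times the mean
    inter-image distance, or when the energy profile E(α) has changed by
    less than ``tol_energy``·8πk per image over the last
    ``energy_window`` cycles (the observable of interest can be stationary
    while images still creep tangentially).
    """

    max_cycles: int = 400
    inner_iters: int = 6
    tol_displacement: float = 5e-3
    tol_energy: float = 2e-4
    energy_window: int = 25
    trust_factor: float = 0.2
    guard_margin: float = 1.0
    guard_ceiling: float = 2.5
    quant_range: tuple[float, float] = (-0.5, 1.5)
    refresh_every: int = 8
    spacing_spec: tuple[int, str] | None = None
    precond_shift: float = 1e-3
    sanity_bound: float = 1.5
    verbose: bool = False
    min_cycles: int = 20


# ---------------------------------------------------------------------------
# path construction


def _weighted_norm(ws: _Workspace, d: np.ndarray) -> float:
    return math.sqrt(float(ws.eops.weights @ (d * d)))


def _project_constraints(phi: np.ndarray, ws: _Workspace,
                         params: ElasticParams, cons: ConstraintSet,
                         iters: int = 4) -> np.ndarray:
    """Minimal-norm Newton correction bringing (A, V) onto their targets.

    Moves ϕ only along the two constraint-gradient directions, leaving the
    shape otherwise untouched; used to initialize interior images.
    """
    from .energetics import area_functional, volume_functional

    phi = phi.copy()
    for _ in range(iters):
        f = ScalarField(ws.grid, phi.reshape(ws.grid.shape))
        cA = area_functional(f, params) - cons.A0
        cV = volume_functional(f) - cons.V0
        if abs(cA) < 1e-10 * cons.A0 and abs(cV) < 1e-10 * cons.V0:
            break
        gA = grad_area(phi, ws.eops, params)[ws.idx]
        gV = grad_volume(phi, ws.eops)[ws.idx]
        dA = gA / ws.w_int
        dV = gV / ws.w_int
        J = np.array([[gA @ dA, gA @ dV], [gV @ dA, gV @ dV]])
        rhs = -np.array([cA, cV])
        try:
            xy = np.linalg.solve(J, rhs)
        except np.linalg.LinAlgError:
            break
        phi[ws.idx] += xy[0] * dA + xy[1] * dV
    return phi


def init_path(
    phiA: ScalarField,
    phiB: ScalarField,
    N: int,
    params: ElasticParams,
    cons: ConstraintSet,
    project: bool | None = None,
    presmooth_iters: int = 0,
    interpolation: str = "distance",
) -> StringPath:
    """Initial string from two endpoint states by pointwise interpolation.

    Endpoints must satisfy the shared constraints (within 10× their
    tolerances) and are stored bit-identical.  With the default
    ``interpolation="distance"`` the approximate signed distance
    d = √2 ϵ atanh(ϕ) of each endpoint is blended and mapped back through
    tanh, so every interior image is a clean single-profile membrane state
    and a topology change appears as a neck radius passing through zero;
    such blends sit within ~1% of the shared area/volume targets and the
    per-image augmented-Lagrangian enforcement during string relaxation
    tightens them further, so no projection is applied by default.
    ``"linear"`` blends ϕ directly (the raw L² geodesic), which superposes
    the two interfaces and starts far from the tanh manifold; in that mode
    a constraint-projection sweep runs by default, and
    ``presmooth_iters`` > 0 adds a short bending-only (kG = 0, bounded
    below) constrained descent pulling images onto the manifold — the
    Gaussian functional is only meaningful near it.
    """
    if N < 2:
        raise ValueError("a path needs at least 2 images")
    if phiA.grid != phiB.grid:
        raise ValueError("endpoint fields must share one grid")
    from .energetics import area_functional, volume_functional

    for name, f in (("A", phiA), ("B", phiB)):
        eA = abs(area_functional(f, params) - cons.A0) / cons.A0
        eV = abs(volume_functional(f) - cons.V0) / cons.V0
        if eA > 10 * cons.tol_A or eV > 10 * cons.tol_V:
            raise ValueError(
                f"endpoint {name} violates the shared constraints "
                f"(area {eA:.2e}, volume {eV:.2e})"
            )
    ws = _Workspace(phiA.grid, params, shift=1e-3)
    params_b = replace(params, kG=0.0)
    if project is None:
        project = interpolation == "linear"
    a = phiA.values.ravel()
    b = phiB.values.ravel()
    if np.array_equal(a, b):
        images = [phiA.copy() for _ in range(N)]
        return StringPath(images=images, alpha=np.linspace(0.0, 1.0, N),
                          params=params, cons=cons)
    if interpolation == "distance":
        cap = 1.0 - 1e-10
        e = params.eps
        a = np.arctanh(np.clip(a, -cap, cap)) * math.sqrt(2) * e
        b = np.arctanh(np.clip(b, -cap, cap)) * math.sqrt(2) * e
    elif interpolation != "linear":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    images = [phiA.copy()]
    for i in range(1, N - 1):
        t = i / (N - 1)
        phi = (1.0 - t) * a + t * b
        if interpolation == "distance":
            phi = np.tanh(phi / (math.sqrt(2) * params.eps))
        if project:
            phi = _project_constraints(phi, ws, params, cons)
        if presmooth_iters > 0:
            smoother = _ImageRelaxer(ws, params_b, cons)
            phi, _ = smoother.step(phi, presmooth_iters, refresh=True,
                                   sanity_bound=1.5, max_move=0.0)
            phi = _project_constraints(phi, ws, params, cons)
        images.append(ScalarField(phiA.grid, phi.reshape(phiA.grid.shape)))
    if N > 1:
        images.append(phiB.copy())
    flats = [im.values.ravel() for im in images]
    e_ends = [energy_breakdown(f, params).E for f in (phiA, phiB)]
    scale8 = 8.0 * math.pi * params.k
    if _heal_path(flats, ws, params, min(e_ends) - scale8,
                  max(e_ends) + 2.5 * scale8):
        images = [images[0]] + [
            ScalarField(phiA.grid, f.reshape(phiA.grid.shape))
            for f in flats[1:-1]
        ] + [images[-1]]
    path = StringPath(images=images, alpha=np.linspace(0.0, 1.0, N),
                      params=params, cons=cons)
    path.alpha = _arclengths(path, ws)
    return path


def _arclengths(path: StringPath, ws: _Workspace) -> np.ndarray:
    d = [0.0]
    for i in range(1, path.n_images):
        d.append(_weighted_norm(
            ws, path.images[i].values.ravel() - path.images[i - 1].values.ravel()))
    cum = np.cumsum(d)
    total = cum[-1]
    return cum / total if total > 0 else np.linspace(0, 1, path.n_images)


def reparametrize(
    path: StringPath,
    spacing_spec: tuple[int, str] | None = None,
    anchor: int | None = None,
    sweeps: int = 6,
) -> StringPath:
    """Redistribute images to equal L² spacing along the piecewise-linear
    path (per segment when a spacing split is requested).

    ``spacing_spec = (n_first, "min")`` keeps the image count split around
    an anchor (by default the lowest interior energy minimum): ``n_first``
    images cover [start, anchor] uniformly, the rest cover (anchor, end].
    Endpoints are never moved; an already equispaced path is returned
    unchanged up to interpolation roundoff.  Because re-interpolated
    images sit on chords of a curved path, a single redistribution leaves
    a small spacing imbalance; up to ``sweeps`` passes are applied until
    consecutive distances agree within 0.5%.
    """
    for _ in range(max(1, sweeps)):
        path = _reparametrize_once(path, spacing_spec, anchor)
        seg = np.diff(path.alpha)
        seg = seg[seg > 0]
        if spacing_spec is not None or len(seg) == 0:
            break  # segmented targets are honored by a single pass per sweep
        if seg.max() / seg.min() <= 1.005:
            break
    return path


def rescale_field(phi: ScalarField, grid_new: AxisymGrid, scale: float,
                  params: ElasticParams) -> ScalarField:
    """Geometrically rescale a membrane state by ``scale`` while keeping
    the interface width ϵ fixed.

    Works in the signed-distance representation: d_new(x) = s·d_old(x/s),
    evaluated by bilinear interpolation of the source distance field, so
    the shape grows (or shrinks) by s but the tanh profile stays an
    ϵ-width profile.  Used for scale continuation: converge a path at a
    cheap, small vesicle size, then rescale it toward the sharp-interface
    regime and polish.
    """
    from scipy.interpolate import RegularGridInterpolator

    eps = params.eps
    d_old = _to_distance(phi.values.ravel(), eps).reshape(phi.grid.shape)
    interp = RegularGridInterpolator(
        (phi.grid.r, phi.grid.z), d_old, method="cubic",
        bounds_error=False, fill_value=None)
    R, Z = grid_new.meshgrid()
    pts = np.stack([np.clip(R.ravel() / scale, 0.0, phi.grid.r_max),
                    np.clip(Z.ravel() / scale, phi.grid.z_min,
                            phi.grid.z_max)], axis=1)
    d_new = scale * interp(pts).reshape(grid_new.shape)
    return ScalarField(grid_new, _from_distance(d_new, eps))


def rescale_path(path: StringPath, grid_new: AxisymGrid, scale: float,
                 cons_new: ConstraintSet) -> StringPath:
    """Rescale every image of a path (see :func:`rescale_field`)."""
    images = [rescale_field(im, grid_new, scale, path.params)
              for im in path.images]
    out = StringPath(images=images, alpha=path.alpha.copy(),
                     params=path.params, cons=cons_new)
    ws = _Workspace(grid_new, path.params, shift=0.0)
    out.alpha = _arclengths(out, ws)
    return out


def _to_distance(phi: np.ndarray, eps: float) -> np.ndarray:
    cap = 1.0 - 1e-10
    return np.arctanh(np.clip(phi, -cap, cap)) * (math.sqrt(2.0) * eps)


def _from_distance(d: np.ndarray, eps: float) -> np.ndarray:
    return np.tanh(d / (math.sqrt(2.0) * eps))


def _reparametrize_once(
    path: StringPath,
    spacing_spec: tuple[int, str] | None,
    anchor: int | None,
) -> StringPath:
    ws = _Workspace(path.grid, path.params, shift=0.0)
    N = path.n_images
    flats = [im.values.ravel() for im in path.images]
    # arc length lives in the physical phi metric, but interpolation is done
    # in the signed-distance (atanh) representation: blends of translated
    # tanh profiles stay tanh profiles, so redistributing images does not
    # smear interfaces the way chords in phi space do
    eps = path.params.eps
    dflats = [_to_distance(f, eps) for f in flats]
    seg = np.array([_weighted_norm(ws, flats[i + 1] - flats[i])
                    for i in range(N - 1)])
    total = float(seg.sum())
    if total == 0.0:
        return path
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    if spacing_spec is not None:
        n_first, mode = spacing_spec
        if mode != "min":
            raise ValueError(f"unknown spacing mode {mode!r}")
        if anchor is None:
            if not path.energies:
                raise ValueError("spacing split needs energies or an anchor")
            E = path.energy_array()
            interior = np.arange(1, N - 1)
            mins = [i for i in interior if E[i] < E[i - 1] and E[i] < E[i + 1]]
            if not mins:
                raise ValueError("no interior minimum found for the split")
            anchor = min(mins, key=lambda i: E[i])
        if not 0 < n_first < N:
            raise ValueError("n_first must lie strictly inside the image count")
        s_anchor = cum[anchor]
        targets = np.concatenate([
            np.linspace(0.0, s_anchor, n_first),
            np.linspace(s_anchor, total, N - n_first + 1)[1:],
        ])
    else:
        targets = np.linspace(0.0, total, N)

    new_images = [path.images[0].copy()]
    for t in targets[1:-1]:
        j = int(np.searchsorted(cum, t, side="right") - 1)
        j = min(j, N - 2)
        frac = (t - cum[j]) / seg[j] if seg[j] > 0 else 0.0
        if frac < 1e-9:
            vals = flats[j]
        elif frac > 1.0 - 1e-9:
            vals = flats[j + 1]
        else:
            d = (1.0 - frac) * dflats[j] + frac * dflats[j + 1]
            vals = _from_distance(d, eps)
        new_images.append(ScalarField(path.grid, vals.reshape(path.grid.shape)))
    new_images.append(path.images[-1].copy())
    out = replace(path, images=new_images, energies=[], converged=False)
    out.alpha = _arclengths(out, ws)
    return out


# ---------------------------------------------------------------------------
# string relaxation


class _ImageRelaxer:
    """Few-step constrained descent for one image, reusing a cached
    preconditioner factorization across cycles."""

    def __init__(self, ws: _Workspace, params: ElasticParams,
                 cons: ConstraintSet) -> None:
        self.ws = ws
        self.params = params
        self.cons = replace(cons)  # per-image multipliers
        if self.cons.penalty == 0.0:
            self.cons.penalty = 200.0 * 8.0 * math.pi * params.k
        self.age = -1

    def step(self, phi: np.ndarray, inner_iters: int, refresh: bool,
             sanity_bound: float, max_move: float) -> tuple[np.ndarray, float]:
        ws = self.ws
        if refresh or self.lu is None:
            ws.refresh(phi)
            self.lu, self.luT, self.M = ws.lu, ws.luT, ws.M
        else:
            ws.lu, ws.luT, ws.M = self.lu, self.luT, self.M
        u0 = ws.to_u(phi[ws.idx])

        def objective(u):
            full = phi.copy()
            full[ws.idx] = ws.to_phi(u)
            val, g, _ = _al_value_grad(full, ws, self.params, self.cons)
            if not np.isfinite(val):
                raise FloatingPointError("string image diverged")
            return val, ws.grad_to_u(g[ws.idx])

        res = minimize(objective, u0, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=inner_iters, maxcor=10,
                                    ftol=1e-15, gtol=1e-13))
        out = phi.copy()
        out[ws.idx] = ws.to_phi(res.x)
        # trust region: an image may move only a fraction of the image
        # spacing per cycle, or quasi-Newton steps overshoot mid-transition
        move = out - phi
        nrm = _weighted_norm(ws, move)
        capped = max_move > 0.0 and nrm > max_move
        if capped:
            out = phi + move * (max_move / nrm)
        np.clip(out, -sanity_bound, sanity_bound, out=out)
        from .energetics import area_functional, volume_functional

        f = ScalarField(ws.grid, out.reshape(ws.grid.shape))
        cA = (area_functional(f, self.params) - self.cons.A0) / self.cons.A0
        cV = (volume_functional(f) - self.cons.V0) / self.cons.V0
        # first-order multiplier update — but only when the inner stage ran
        # to (approximate) stationarity; updating on a trust-capped step
        # overshoots and sets off a multiplier limit cycle
        if not capped:
            self.cons.mult_A += self.cons.penalty * cA
            self.cons.mult_V += self.cons.penalty * cV
        return out, max(abs(cA), abs(cV))

    lu = None
    luT = None
    M = None


def run_string(path: StringPath, opts: StringOptions | None = None) -> StringPath:
    """Relax a string to (an approximation of) the minimal energy path.

    Alternates a few inner constrained-descent iterations on every
    interior image with an equal-arc-length reparametrization, holding the
    endpoints fixed.  Convergence is declared when the largest image
    displacement in one cycle falls below ``tol_displacement`` times the
    mean inter-image spacing; the displacement history is attached to the
    returned path, with per-image energies."""
    opts = opts or StringOptions()
    ws = _Workspace(path.grid, path.params, shift=opts.precond_shift)
    relaxers = [_ImageRelaxer(ws, path.params, path.cons)
                for _ in range(path.n_images)]
    cur = path
    residuals: list[float] = []
    converged = False
    anchor = None
    scale = 8.0 * math.pi * path.params.k
    e_ends = [energy_breakdown(path.images[j], path.params).E for j in (0, -1)]
    e_floor = min(e_ends) - opts.guard_margin * scale
    e_ceiling = max(e_ends) + opts.guard_ceiling * scale
    for cycle in range(opts.max_cycles):
        refresh = cycle % opts.refresh_every == 0
        before = [im.values.ravel().copy() for im in cur.images]
        flats = [im.values.ravel() for im in cur.images]
        max_move = opts.trust_factor * _mean_spacing(cur, ws)
        for i in range(1, cur.n_images - 1):
            newphi, _ = relaxers[i].step(flats[i], opts.inner_iters, refresh,
                                         opts.sanity_bound, max_move)
            if not _physical_state(newphi, ws, path.params, e_floor,
                                   e_ceiling, opts.quant_range):
                # image escaped toward the unphysical region: discard the
                # step and let reparametrization re-tension the string
                relaxers[i].cons.mult_A = 0.0
                relaxers[i].cons.mult_V = 0.0
                continue
            flats[i] = newphi
        images = [cur.images[0]] + [
            ScalarField(cur.grid, f.reshape(cur.grid.shape))
            for f in flats[1:-1]
        ] + [cur.images[-1]]
        cur = replace(cur, images=images)
        if opts.spacing_spec is not None:
            _attach_energies(cur)
            try:
                cur = reparametrize(cur, opts.spacing_spec, anchor=anchor)
            except ValueError:
                cur = reparametrize(cur)
        else:
            cur = reparametrize(cur)
        # heal any image the redistribution or descent pushed off the
        # physical manifold before it can contaminate its neighbors
        healed_flats = [im.values.ravel() for im in cur.images]
        n_healed = _heal_path(healed_flats, ws, path.params, e_floor,
                              e_ceiling, opts.quant_range)
        if n_healed:
            cur = replace(cur, images=[cur.images[0]] + [
                ScalarField(cur.grid, f.reshape(cur.grid.shape))
                for f in healed_flats[1:-1]
            ] + [cur.images[-1]])
        # net displacement over the full cycle (relaxation + redistribution):
        # tangential sliding that reparametrization undoes does not count
        disp = max(
            _weighted_norm(ws, cur.images[i].values.ravel() - before[i])
            for i in range(1, cur.n_images - 1)
        )
        mean_spacing = _mean_spacing(cur, ws)
        rel = disp / mean_spacing if mean_spacing > 0 else 0.0
        residuals.append(rel)
        if cycle % opts.energy_window == 0 or cycle == opts.max_cycles - 1:
            _attach_energies(cur)
            e_now = cur.energy_array()
            if (cycle >= opts.min_cycles and "e_prev" in locals()
                    and len(e_now) == len(e_prev)
                    and np.abs(e_now - e_prev).max()
                    < opts.tol_energy * scale * opts.energy_window):
                converged = True
            e_prev = e_now
        if opts.verbose and cycle % 10 == 0:
            print(f"[string {cycle:3d}] displacement/spacing = {rel:.3e}")
        if rel < opts.tol_displacement and cycle + 1 >= opts.min_cycles:
            converged = True
        if converged:
            break
    _attach_energies(cur)
    cur.residuals = residuals
    cur.converged = converged
    cur.alpha = _arclengths(cur, ws)
    return cur


def _heal_path(flats: list[np.ndarray], ws: _Workspace,
               params: ElasticParams, e_floor: float, e_ceiling: float,
               quant_range: tuple[float, float] = (-0.5, 1.5),
               max_pass: int = 5) -> int:
    """Replace unphysical interior images by distance-space blends of their
    nearest physical neighbors.

    Off the tanh manifold the discrete Gaussian functional is unbounded
    (for kG < 0) and sub-grid necks produce meaningless energies, so an
    image that drifted into that region cannot be relaxed back; re-seeding
    it between good neighbors keeps the whole string in the physical
    configuration space.  Images that remain unphysical after ``max_pass``
    blending passes (a garbage block whose blends are themselves bad) are
    force-replaced by copies of their nearest good anchor — the following
    reparametrization redistributes the duplicates.  Returns the number of
    replacements.
    """
    n = len(flats)
    eps = params.eps
    healed = 0

    def bad_set():
        return {i for i in range(1, n - 1)
                if not _physical_state(flats[i], ws, params, e_floor,
                                       e_ceiling, quant_range)}

    for attempt in range(max_pass + 1):
        bad = bad_set()
        if not bad:
            break
        force = attempt == max_pass
        for i in sorted(bad):
            lo = i - 1
            while lo > 0 and lo in bad:
                lo -= 1
            hi = i + 1
            while hi < n - 1 and hi in bad:
                hi += 1
            if force:
                flats[i] = flats[lo if i - lo <= hi - i else hi].copy()
            else:
                t = (i - lo) / (hi - lo)
                d = ((1.0 - t) * _to_distance(flats[lo], eps)
                     + t * _to_distance(flats[hi], eps))
                flats[i] = _from_distance(d, eps)
            healed += 1
    return healed


def _physical_state(phi: np.ndarray, ws: _Workspace, params: ElasticParams,
                    e_floor: float, e_ceiling: float = math.inf,
                    quant_range: tuple[float, float] = (-0.5, 1.5)) -> bool:
    """Heuristic guard: a membrane state must keep E above the endpoint
    floor and EG/4πkG within the genus window of the problem.

    For kG < 0 the discrete Gaussian functional rewards nucleating extra
    axisymmetric handles (each drops EG by 4π|kG|), a runaway the
    continuum model does not share; the quantization window blocks it.
    The default (−0.5, 1.5) covers a single vesicle of genus 0 or 1
    mid-transition; widen it (StringOptions.quant_range) for
    multi-vesicle or higher-genus studies, e.g. (0.5, 2.5) for a
    two-vesicle fusion path."""
    from .energetics import bending_energy, gaussian_energy

    f = ScalarField(ws.grid, phi.reshape(ws.grid.shape))
    eg = gaussian_energy(f, params)
    if params.kG != 0.0:
        quant = eg / (4.0 * math.pi * params.kG)
        if not quant_range[0] <= quant <= quant_range[1]:
            return False
    return e_floor <= bending_energy(f, params) + eg <= e_ceiling


def _mean_spacing(path: StringPath, ws: _Workspace) -> float:
    flats = [im.values.ravel() for im in path.images]
    segs = [_weighted_norm(ws, flats[i + 1] - flats[i])
            for i in range(path.n_images - 1)]
    return float(np.mean(segs))


def _attach_energies(path: StringPath) -> None:
    path.energies = [energy_breakdown(im, path.params) for im in path.images]


def refine_segment(path: StringPath, i_lo: int, i_hi: int, N_new: int,
                   opts: StringOptions | None = None) -> StringPath:
    """Re-run a sub-path between images ``i_lo`` and ``i_hi`` with
    ``N_new`` images (e.g. to resolve the steepest stretch of a MEP).

    The endpoints of the refined string are the two chosen images, held
    fixed; denser sampling can only raise the observed maximum along the
    segment (up to interpolation error)."""
    if not 0 <= i_lo < i_hi < path.n_images:
        raise ValueError("need 0 <= i_lo < i_hi < n_images")
    sub = StringPath(
        images=[im.copy() for im in path.images[i_lo:i_hi + 1]],
        alpha=path.alpha[i_lo:i_hi + 1].copy(),
        params=path.params, cons=path.cons,
    )
    ws = _Workspace(path.grid, path.params, shift=0.0)
    sub.alpha = _arclengths(sub, ws)
    # resample to N_new images, then relax
    targets = np.linspace(0.0, 1.0, N_new)
    flats = [im.values.ravel() for im in sub.images]
    eps = path.params.eps
    dflats = [_to_distance(f, eps) for f in flats]
    cum = sub.alpha
    images = []
    for t in targets:
        j = min(int(np.searchsorted(cum, t, side="right") - 1), len(flats) - 2)
        den = cum[j + 1] - cum[j]
        frac = (t - cum[j]) / den if den > 0 else 0.0
        if frac < 1e-9:
            vals = flats[j]
        elif frac > 1.0 - 1e-9:
            vals = flats[j + 1]
        else:
            vals = _from_distance((1.0 - frac) * dflats[j]
                                  + frac * dflats[j + 1], eps)
        images.append(ScalarField(path.grid, vals.reshape(path.grid.shape)))
    sub = replace(sub, images=images, alpha=targets.copy(), energies=[])
    return run_string(sub, opts)


# ---------------------------------------------------------------------------
# path analysis


@dataclass
class PathAnalysis:
    """Critical points and barriers of a converged path.

    ``barriers`` contains the forward/backward barriers over the highest
    saddle plus, for every interior minimum i, the escape barriers
    ``escape_<i>_forward`` / ``escape_<i>_backward``.  ``eg_quantization``
    gives EG/4πkG per image (≈ integer 1−g away from the transition).
    """

    minima_indices: list[int]
    saddle_indices: list[int]
    barriers: dict[str, float]
    alpha: np.ndarray
    E: np.ndarray
    EG: np.ndarray
    eg_quantization: np.ndarray


def _prune_extrema(E: np.ndarray, minima: list[int], saddles: list[int],
                   tol: float) -> tuple[list[int], list[int]]:
    """Persistence pruning: drop adjacent saddle/minimum pairs whose energy
    difference is below ``tol`` (numerical ripple on plateaus)."""
    changed = True
    while changed and saddles:
        changed = False
        crit = sorted([(i, "min") for i in minima] + [(i, "max") for i in saddles])
        for j in range(len(crit) - 1):
            i1, t1 = crit[j]
            i2, t2 = crit[j + 1]
            if t1 != t2 and abs(E[i2] - E[i1]) < tol:
                # remove the pair, but never an endpoint minimum
                drop = {i for i, t in ((i1, t1), (i2, t2))
                        if not (t == "min" and (i == 0 or i == len(E) - 1))}
                if len(drop) == 2:
                    minima = [i for i in minima if i not in drop]
                    saddles = [i for i in saddles if i not in drop]
                    changed = True
                    break
    return minima, saddles


def analyze_path(path: StringPath, tol: float = 0.0) -> PathAnalysis:
    """Locate minima, saddles and barriers of the energy profile.

    ``tol`` (absolute energy) suppresses extrema whose prominence is below
    numerical ripple; barriers are saddle minus basin energies and are
    non-negative by construction.
    """
    if path.n_images < 3:
        raise ValueError("path analysis needs at least 3 images")
    if not path.energies:
        _attach_energies(path)
    E = path.energy_array()
    N = len(E)
    minima = [i for i in range(1, N - 1) if E[i] < E[i - 1] and E[i] < E[i + 1]]
    saddles = [i for i in range(1, N - 1) if E[i] > E[i - 1] and E[i] > E[i + 1]]
    if E[0] < E[1]:
        minima.insert(0, 0)
    if E[-1] < E[-2]:
        minima.append(N - 1)
    if tol > 0:
        minima, saddles = _prune_extrema(E, minima, saddles, tol)

    barriers: dict[str, float] = {}
    if saddles:
        top = max(E[i] for i in saddles)
        # an endpoint above every saddle sees no barrier at all
        barriers["forward"] = max(0.0, top - E[0])
        barriers["backward"] = max(0.0, top - E[-1])
    for i in minima:
        if i in (0, N - 1):
            continue
        right = [s for s in saddles if s > i]
        left = [s for s in saddles if s < i]
        if right:
            barriers[f"escape_{i}_forward"] = E[right[0]] - E[i]
        if left:
            barriers[f"escape_{i}_backward"] = E[left[-1]] - E[i]

    EG = np.array([bd.EG for bd in path.energies])
    kG = path.params.kG
    quant = EG / (4.0 * math.pi * kG) if kG != 0 else np.full(N, np.nan)
    return PathAnalysis(
        minima_indices=minima,
        saddle_indices=saddles,
        barriers=barriers,
        alpha=path.alpha.copy(),
        E=E,
        EG=EG,
        eg_quantization=quant,
    )
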