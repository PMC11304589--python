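"""Lateral stress profile of the flat diffuse-interface membrane.

Across a planar bilayer the in-plane stress s(z) varies with the depth z
(normal to the membrane plane, z < 0 toward the inner leaflet).  For a
Ginzburg-Landau interface the bending part of the free energy can be put
in the Gompper-Zschocke form ∫[c(∇²ϕ)² + g(ϕ)|∇ϕ|² + f(ϕ)]dV with

    c    = 3kϵ/(4√2),
    g(ϕ) = 3k(3ϕ² − 1 + 2√2 m ϵ ϕ)/(2√2 ϵ),
    f(ϕ) = 3k(ϕ²−1)²(ϕ+√2ϵm)²/(4√2 ϵ³),

whose lateral stress on the planar solution ϕ0(z/ϵ) = tanh(−z/(√2ϵ)) is

    sb(z) = 2 g(ϕ0) ϕ0′²/ϵ² + 4c ϕ0″²/ϵ⁴            (bending part),
    sG(z) = 35 kG (12 ϕ0′²ϕ0″² + 4 ϕ0′³ϕ0‴)/(16√2 ϵ³)  (Gaussian part),

primes denoting derivatives with respect to z/ϵ.  The total profile
s = sb + sG satisfies the elastic moment identities

    ∫ s dz   = Σ̂ = 2km²   (spontaneous tension),
    ∫ z s dz = −2km,
    ∫ z²s dz = kG + 2k,

and its central peak s(0) vanishes exactly at kG/k = −24/35.

Model energies are in kBT and lengths in nm; pressures are reported in
bar (1 bar = 10⁵ Pa) using the configurable kBT→joule constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .energetics import ElasticParams

__all__ = [
    "planar_profile",
    "stress_bending",
    "stress_gaussian",
    "stress_total",
    "stress_moments",
    "central_zero_ratio",
    "StressProfile",
    "StressMoments",
]

SQRT2 = math.sqrt(2.0)

#: quadrature truncation, in units of ϵ (tanh tails decay like e^(−√2 z/ϵ))
MOMENT_CUTOFF = 12.0

#: pressure unit conversion
PASCAL_PER_BAR = 1.0e5


def planar_profile(z, params: ElasticParams):
    """Planar interface profile ϕ0 = tanh(−z/(√2ϵ)) and its derivatives.

    Returns ``(phi0, d1, d2, d3)`` where the derivatives are taken with
    respect to the stretched coordinate z/ϵ (so ϕ0′(0) = −1/√2).
    """
    # with t = tanh(-x/√2), x = z/ϵ:  dt/dx = -(1-t²)/√2
    t = np.tanh(-np.asarray(z, dtype=float) / (SQRT2 * params.eps))
    sech2 = 1.0 - t * t
    d1 = -sech2 / SQRT2
    d2 = -t * sech2
    d3 = (1.0 - 3.0 * t * t) * sech2 / SQRT2
    return t, d1, d2, d3


def _gz_coefficients(params: ElasticParams) -> tuple[float, float]:
    """(c, prefactor of sG) in model units."""
    k, e = params.k, params.eps
    c = 3.0 * k * e / (4.0 * SQRT2)
    gpref = 35.0 * params.kG / (16.0 * SQRT2 * e**3)
    return c, gpref


def _g_of_phi(phi, params: ElasticParams):
    k, e, m = params.k, params.eps, params.m
    return 3.0 * k * (3.0 * phi * phi - 1.0 + 2.0 * SQRT2 * m * e * phi) / (
        2.0 * SQRT2 * e
    )


def stress_bending(z, params: ElasticParams):
    """Bending contribution sb(z) in model units (kBT/length³)."""
    phi0, d1, d2, _ = planar_profile(z, params)
    c, _ = _gz_coefficients(params)
    e = params.eps
    return 2.0 * _g_of_phi(phi0, params) * d1 * d1 / e**2 + 4.0 * c * d2 * d2 / e**4


def stress_gaussian(z, params: ElasticParams):
    """Gaussian contribution sG(z) in model units."""
    _, d1, d2, d3 = planar_profile(z, params)
    _, gpref = _gz_coefficients(params)
    return gpref * (12.0 * d1 * d1 * d2 * d2 + 4.0 * d1**3 * d3)


def _to_bar(s_model, params: ElasticParams) -> np.ndarray:
    """Convert kBT/nm³ to bar."""
    pa = np.asarray(s_model) * params.kBT_joules / 1.0e-27
    return pa / PASCAL_PER_BAR


@dataclass(frozen=True)
class StressMoments:
    """Zeroth, first and second moments of s(z): tension, torque and
    second-moment combinations of the elastic constants."""

    m0: float
    m1: float
    m2: float

    def as_dict(self) -> dict[str, float]:
        return {"m0": self.m0, "m1": self.m1, "m2": self.m2}


@dataclass
class StressProfile:
    """Sampled lateral stress profile with unit conversions attached."""

    z: np.ndarray
    sb: np.ndarray
    sG: np.ndarray
    params: ElasticParams

    @property
    def s(self) -> np.ndarray:
        return self.sb + self.sG

    @property
    def sb_bar(self) -> np.ndarray:
        return _to_bar(self.sb, self.params)

    @property
    def sG_bar(self) -> np.ndarray:
        return _to_bar(self.sG, self.params)

    @property
    def s_bar(self) -> np.ndarray:
        return _to_bar(self.s, self.params)

    def extrema(self) -> dict[str, float]:
        """Global maximum and the two flanking minima of s(z), in bar,
        located by dense sampling plus local parabolic refinement."""
        e = self.params.eps
        zz = np.arange(-8.0 * e, 8.0 * e + 1e-12, e / 200.0)
        ss = _to_bar(stress_bending(zz, self.params)
                     + stress_gaussian(zz, self.params), self.params)

        def refine(i: int) -> tuple[float, float]:
            if 0 < i < len(zz) - 1:
                y0, y1, y2 = ss[i - 1], ss[i], ss[i + 1]
                denom = y0 - 2.0 * y1 + y2
                if denom != 0.0:
                    d = 0.5 * (y0 - y2) / denom
                    h = zz[1] - zz[0]
                    return zz[i] + d * h, y1 - 0.25 * (y0 - y2) * d
            return zz[i], ss[i]

        imax = int(np.argmax(ss))
        z_max, s_max = refine(imax)
        minima = [refine(i) for i in range(1, len(zz) - 1)
                  if ss[i] < ss[i - 1] and ss[i] <= ss[i + 1]]
        minima.sort(key=lambda t: t[1])
        out = {"z_max": z_max, "s_max": s_max}
        if minima:
            out["s_min"] = minima[0][1]
            out["z_min"] = minima[0][0]
        if len(minima) > 1:
            out["s_min2"] = minima[1][1]
            out["z_min2"] = minima[1][0]
        return out


def stress_total(params: ElasticParams, z_grid=None) -> StressProfile:
    """Full profile s = sb + sG sampled on ``z_grid`` (default: dense
    samples over |z| ≤ 8ϵ)."""
    if z_grid is None:
        e = params.eps
        z_grid = np.linspace(-8.0 * e, 8.0 * e, 1601)
    z_grid = np.asarray(z_grid, dtype=float)
    return StressProfile(
        z=z_grid,
        sb=stress_bending(z_grid, params),
        sG=stress_gaussian(z_grid, params),
        params=params,
    )


def tension_density(z, params: ElasticParams):
    """Spontaneous-tension density of a flat membrane with m ≠ 0.

    A flat tanh membrane with spontaneous curvature m is frustrated: its
    bending density does not vanish, ΨB[ϕ0] = √2 m sech²(z/√2ϵ)/ϵ, leaving
    the excess free energy per unit area (3kϵ/4√2)∫ΨB²dz = 2km² — exactly
    the spontaneous tension Σ̂.  This O(m²) density is dropped by the
    symmetric-membrane closed form of sb(z) (whose zeroth moment therefore
    vanishes identically) and is restored here for the tension moment.
    """
    phi0, _, _, _ = planar_profile(z, params)
    e = params.eps
    psi = SQRT2 * params.m * (1.0 - phi0 * phi0) / e
    return (3.0 * params.k * e / (4.0 * SQRT2)) * psi * psi


def stress_moments(params: ElasticParams, quad_tol: float = 1e-10) -> StressMoments:
    """Moments of the lateral stress by adaptive quadrature over |z| ≤ 12ϵ.

    m0 = 2km² (spontaneous tension), m1 = −2km, m2 = kG + 2k, each
    reproduced to ~1e-6 relative (the tanh tails make the truncation error
    exponentially small).  The zeroth moment integrates s(z) plus the
    spontaneous-tension density (see :func:`tension_density`); the first
    and second moments integrate the profile as printed — the tension
    density is even in z, so it cannot contribute a torque, and its
    O(m²ϵ²) second moment lies beyond the order at which the elastic
    constants are defined in the λ ≪ 1 expansion.
    """
    e = params.eps
    lim = MOMENT_CUTOFF * e

    def total(z):
        return stress_bending(z, params) + stress_gaussian(z, params)

    integrands = [
        lambda z: total(z) + tension_density(z, params),
        lambda z: z * total(z),
        lambda z: z * z * total(z),
    ]
    out = []
    for n, f in enumerate(integrands):
        val, err = quad(f, -lim, lim, epsabs=quad_tol, epsrel=quad_tol,
                        limit=400)
        scale = max(params.k, abs(params.kG)) / e ** (2 - n)
        if err > 1e-6 * max(abs(val), scale):
            raise RuntimeError(
                f"moment quadrature did not converge (order {n}, "
                f"estimated error {err:g})"
            )
        out.append(val)
    return StressMoments(*out)


def central_zero_ratio() -> Fraction:
    """The kG/k ratio at which the mid-plane stress s(0) vanishes.

    At z = 0 (m = 0): ϕ0 = 0, ϕ0′² = 1/2, ϕ0″ = 0, ϕ0‴ = 1/√2, so
    sb(0) = −3k/(2√2ϵ³) and sG(0) = −35kG/(16√2ϵ³); the root of
    sb(0) + sG(0) = 0 is kG/k = −(3/2)·(16/35) = −24/35 exactly.
    """
    sb0 = Fraction(-3, 2)    # sb(0)·(√2ϵ³)/k
    sG0 = Fraction(-35, 16)  # sG(0)·(√2ϵ³)/kG
    return -sb0 / sG0


def central_zero_bracket(params_template: ElasticParams | None = None
                         ) -> float:
    """Numerical cross-check: bracket the sign change of s(0) in kG/k."""
    k = params_template.k if params_template else 20.0
    eps = params_template.eps if params_template else 5.0 / 6.0

    def s0(ratio: float) -> float:
        p = ElasticParams(k=k, kG=ratio * k, m=0.0, eps=eps)
        return float(stress_bending(0.0, p) + stress_gaussian(0.0, p))

    return brentq(s0, -1.0, -0.5, xtol=1e-14)
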