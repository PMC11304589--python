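"""Lateral stress profile: closed forms, moment identities, extrema."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memphase import (
    ElasticParams,
    central_zero_ratio,
    planar_profile,
    stress_bending,
    stress_gaussian,
    stress_moments,
    stress_total,
)
from memphase.stress import central_zero_bracket

SQRT2 = math.sqrt(2.0)


@pytest.fixture(scope="module")
def p_ref():
    return ElasticParams(k=20.0, kG=-20.0, m=0.0, eps=5.0 / 6.0)


def test_planar_profile_values_at_origin(p_ref):
    phi0, d1, d2, d3 = planar_profile(0.0, p_ref)
    assert phi0 == pytest.approx(0.0, abs=1e-15)
    assert d1 == pytest.approx(-1.0 / SQRT2)
    assert d2 == pytest.approx(0.0, abs=1e-15)
    assert d3 == pytest.approx(1.0 / SQRT2)
    # limits
    far = planar_profile(np.array([-50.0, 50.0]), p_ref)[0]
    assert far == pytest.approx([1.0, -1.0])


def test_planar_profile_derivatives_match_finite_differences(p_ref):
    z = np.linspace(-4.0, 4.0, 81)
    h = 1e-5 * p_ref.eps
    phi0, d1, d2, d3 = planar_profile(z, p_ref)
    eps = p_ref.eps
    fd1 = (planar_profile(z + h, p_ref)[0] - planar_profile(z - h, p_ref)[0]) \
        / (2.0 * h) * eps
    fd2 = (planar_profile(z + h, p_ref)[1] - planar_profile(z - h, p_ref)[1]) \
        / (2.0 * h) * eps
    fd3 = (planar_profile(z + h, p_ref)[2] - planar_profile(z - h, p_ref)[2]) \
        / (2.0 * h) * eps
    assert np.abs(fd1 - d1).max() < 1e-8
    assert np.abs(fd2 - d2).max() < 1e-8
    assert np.abs(fd3 - d3).max() < 1e-8


def test_stress_values_at_origin(p_ref):
    """sb(0) = −3k/(2√2ϵ³) and sG(0) = −35kG/(16√2ϵ³) by substitution."""
    e = p_ref.eps
    assert stress_bending(0.0, p_ref) == pytest.approx(
        -3.0 * p_ref.k / (2.0 * SQRT2 * e**3))
    assert stress_gaussian(0.0, p_ref) == pytest.approx(
        -35.0 * p_ref.kG / (16.0 * SQRT2 * e**3))


def test_central_zero_ratio_exact():
    from fractions import Fraction

    ratio = central_zero_ratio()
    assert ratio == Fraction(-24, 35)
    # numerical bracketing of the same root
    assert central_zero_bracket() == pytest.approx(-24.0 / 35.0, abs=1e-12)
    # consistency: total stress vanishes at the mid-plane at that ratio
    p = ElasticParams(k=20.0, kG=20.0 * float(ratio), m=0.0, eps=5.0 / 6.0)
    prof = stress_total(p)
    assert abs(prof.s[len(prof.z) // 2]) < 1e-12 * np.abs(prof.s).max()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    k=st.floats(5.0, 40.0),
    ratio=st.floats(-2.0, -0.01),
    m=st.floats(-0.1, 0.1),
)
def test_moment_identities(k, ratio, m):
    """∫s = 2km², ∫zs = −2km, ∫z²s = kG + 2k over the stability range."""
    p = ElasticParams(k=k, kG=ratio * k, m=m, eps=5.0 / 6.0)
    mom = stress_moments(p)
    scale = k
    assert mom.m0 == pytest.approx(2.0 * k * m * m, abs=1e-6 * scale)
    assert mom.m1 == pytest.approx(-2.0 * k * m, abs=1e-6 * scale)
    assert mom.m2 == pytest.approx(ratio * k + 2.0 * k, abs=1e-6 * scale)


def test_profile_scales_linearly_with_k():
    z = np.linspace(-5.0, 5.0, 201)
    p1 = ElasticParams(k=10.0, kG=-10.0, m=0.0, eps=5.0 / 6.0)
    p2 = ElasticParams(k=20.0, kG=-20.0, m=0.0, eps=5.0 / 6.0)
    s1 = stress_total(p1, z).s
    s2 = stress_total(p2, z).s
    assert np.allclose(s2, 2.0 * s1, rtol=1e-13, atol=0.0)


def test_symmetry_and_mirror_asymmetry():
    z = np.linspace(-6.0, 6.0, 241)
    p0 = ElasticParams(k=20.0, kG=-14.0, m=0.0, eps=5.0 / 6.0)
    s0 = stress_total(p0, z).s
    assert np.allclose(s0, s0[::-1], rtol=1e-10)
    pp = ElasticParams(k=20.0, kG=-14.0, m=+0.05, eps=5.0 / 6.0)
    pm = ElasticParams(k=20.0, kG=-14.0, m=-0.05, eps=5.0 / 6.0)
    sp = stress_total(pp, z).s
    sm = stress_total(pm, z).s
    assert np.allclose(sp, sm[::-1], rtol=1e-12)   # mirror images
    assert not np.allclose(sp, sp[::-1], rtol=1e-3)  # genuinely asymmetric


def test_central_bump_grows_as_kG_decreases():
    """At kG = 0 the mid-plane is repulsive; lowering kG raises the central
    bump and lowers the head-group peaks (leaflet-insertion trends)."""
    center, peaks = [], []
    for ratio in (0.0, -0.5, -1.0, -1.5):
        p = ElasticParams(k=20.0, kG=20.0 * ratio, m=0.0, eps=5.0 / 6.0)
        prof = stress_total(p)
        s = prof.s_bar
        center.append(s[len(s) // 2])
        # head-group peak: maximum away from the mid-plane
        off = np.abs(prof.z) > 1.5 * p.eps
        peaks.append(s[off].max())
    assert center[0] < 0.0
    assert all(b > a for a, b in zip(center, center[1:]))
    assert all(b < a for a, b in zip(peaks, peaks[1:]))


def test_decay_and_units(p_ref):
    e = p_ref.eps
    z = np.array([9.0 * e, 12.0 * e, -10.0 * e])
    prof_far = np.abs(stress_bending(z, p_ref) + stress_gaussian(z, p_ref))
    peak = np.abs(stress_total(p_ref).s).max()
    assert prof_far.max() < 1e-6 * peak
    # bar conversion: kBT/nm³ ≈ 41.1 bar at the default constant
    one = ElasticParams(k=20.0, kG=-20.0, m=0.0, eps=5.0 / 6.0)
    prof = stress_total(one)
    assert prof.s_bar == pytest.approx(prof.s * 41.1, rel=1e-10)
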