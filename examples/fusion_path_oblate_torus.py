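"""Minimal energy path for piercing a vesicle: oblate ↔ Clifford torus.

Computes a scaled-down string-method MEP between the relaxed oblate
vesicle and the Clifford torus at shared area and volume (v ≈ 0.71,
kG = −k).  The converged energy profile shows the hemifusion-like
metastable intermediate between two saddle points; crossing it changes
the genus from 0 to 1, and the Gaussian energy jump 4π|kG| is partially
screened by the bending energy.

This desk-scale run (λ ≈ 0.018, a few minutes) reproduces the structure
of the transition; barrier heights sharpen toward their sharp-interface
values as λ decreases and the image count grows.
"""

import dataclasses
import math

from memphase import (
    AxisymGrid,
    ConstraintSet,
    ElasticParams,
    RelaxOptions,
    ShapeSpec,
    StringOptions,
    analyze_path,
    init_path,
    make_shape,
    relax,
    run_string,
)
from memphase.shapes import (
    CLIFFORD_RATIO,
    oblate_aspect_for_reduced_volume,
    spheroid_area_volume,
)

params = ElasticParams(k=20.0, kG=-20.0, m=0.0, eps=1.0)
Dve = 56.0  # lambda = eps/Dve ~ 0.018

# analytic area/volume targets from the Clifford torus geometry
r_tube = Dve / math.sqrt(4.0 * math.pi * CLIFFORD_RATIO)
A0 = 4.0 * math.pi**2 * CLIFFORD_RATIO * r_tube**2
V0 = 2.0 * math.pi**2 * CLIFFORD_RATIO * r_tube**3
v_target = V0 / (math.pi * math.sqrt(A0 / math.pi) ** 3 / 6.0)

aspect = oblate_aspect_for_reduced_volume(v_target)
a_eq = Dve * math.sqrt(math.pi / spheroid_area_volume(1.0, aspect)[0])
r_ext = max(a_eq, r_tube * (1.0 + CLIFFORD_RATIO)) + 8.0
z_ext = max(a_eq * aspect, r_tube) + 8.0
grid = AxisymGrid.from_extents(r_ext, -z_ext, z_ext, spacing=2.0 / 3.0)

ends = []
for spec in (ShapeSpec(kind="ellipsoid", v=v_target, Dve=Dve),
             ShapeSpec(kind="clifford_torus", Dve=Dve)):
    res = relax(make_shape(spec, grid, params), params,
                ConstraintSet(A0=A0, V0=V0), RelaxOptions(inner_maxiter=400))
    ends.append(res.phi_star)

path = init_path(ends[0], ends[1], 26, params, ConstraintSet(A0=A0, V0=V0))
path = run_string(path, StringOptions(max_cycles=250))

scale = 8.0 * math.pi * params.k
ana = analyze_path(path, tol=2e-3 * scale)
print("alpha    E/8pik   EG/4pikG")
for al, bd in zip(path.alpha, path.energies):
    print(f"{al:5.3f}  {bd.E / scale:8.4f}  "
          f"{bd.EG / (4 * math.pi * params.kG):8.3f}")
print("minima at images:", ana.minima_indices)
print("saddles at images:", ana.saddle_indices)
for name, val in ana.barriers.items():
    print(f"{name:24s} {val / scale:6.3f} * 8πk  = {val:7.1f} kBT")
# The interior minimum is the hemifusion-like intermediate; EG/4πkG drops
# from 1 (genus 0) to 0 (genus 1) across the merging window while the
# forward barrier builds up continuously with the large-scale deformation.
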