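# Methods

## Model

A fluid lipid vesicle is described by a phase field ϕ(x) on an
axisymmetric domain: ϕ = +1 inside, −1 outside, and the bilayer
mid-surface is the ϕ = 0 level set of the diffuse transition layer.  The
free energy is a Ginzburg–Landau functional E[ϕ] = EB[ϕ] + EG[ϕ]:

    EB = (3kϵ/4√2) ∫ ΨB² dV,      ΨB = ∇²ϕ − (1/ϵ²)(ϕ²−1)(ϕ+√2ϵm),
    EG = (35 kG ϵ³/16√2) ∫ ΨG dV,
    ΨG = ∇|∇ϕ|²·∇|∇ϕ|²/2 − (∇|∇ϕ|²·∇ϕ)∇²ϕ
         + |∇ϕ|²[(∇²ϕ)² + ∇ϕ·∇∇²ϕ − ∇²|∇ϕ|²/2].

In the sharp-interface limit λ = ϵ/Dve ≪ 1 (Dve = √(A/π) the vesicle
diameter) these recover the Canham–Helfrich energy 2k∫(M−m)²dS + kG∫G dS.
By Gauss–Bonnet the Gaussian part is topological, EG → 4πkG(1−g), so it
is constant except across fusion/fission events — which the diffuse
interface, unlike the sharp model, crosses smoothly.  Membrane area and
enclosed volume are measured by

    A[ϕ] = (3ϵ/4√2) ∫ [(1−ϕ²)²/2ϵ² + |∇ϕ|²] dV,    V[ϕ] = ∫ (1+ϕ)/2 dV.

The prefactors are fixed by two exact identities used as unit tests: the
planar profile ϕ0 = tanh(−z/√2ϵ) carries unit area density
((3ϵ/4√2)∫[(1−ϕ0²)²/2ϵ² + ϕ0′²]dz = 1), and a large sphere carries
EG = 4πkG (via ∫sech⁸ = 32/35).  Both identities require ϵ in the
*numerator* of the field-functional prefactors; they are also consistent
with the Gompper–Zschocke coefficient c = 3kϵ/4√2 of the rewritten
bending energy (see the stress profile below).

### Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| k   | bending rigidity          | 20    | kBT |
| kG  | Gaussian modulus          | −k    | kBT; stability needs −2 ≤ kG/k ≤ 0 |
| m   | bilayer spontaneous curvature | 0 | 1/length |
| ϵ   | interface width parameter | 5/6   | nm; bilayer thickness ℓme = 6ϵ = 5 nm |
| kBT | thermal energy            | 4.11×10⁻²¹ | J (≈ 298 K) |

The thickness matching 6ϵ = 5 nm sets the absolute scale of every
simulation (topological transitions are not scale invariant: the distance
at which membranes interact is set by ϵ).  Simulations run with lengths
in units of ϵ; only the stress module converts to SI.  kBT = 4.11×10⁻²¹ J
makes k = 20 kBT with ϵ = 5/6 nm give a ≈2,890 bar stress maximum for
kG = −2k; the temperature behind the conversion is a convention of this
package.

## Discretization

Fields live on a uniform grid in the r–z half plane with equal spacing in
both directions, default h = 2ϵ/3 (≥ 9 nodes across the ≈ 6ϵ interface).
Boundary conditions are Dirichlet ϕ = −1 on the outer walls (vesicle
exterior); on the axis the operators use the even-symmetry closure
∇²f|₀ = 4(f(Δr) − f(0))/Δr² + ∂²f/∂z².  Volume quadrature uses exact
cell integrals of the 2πr weight radially (the axis node gets πΔr²/4 —
never zero, which matters when dividing nodal gradients by weights) and
the trapezoid rule axially.

The public grid operators (`laplacian`, `gradient`, `integrate`) are the
standard second-order stencils.  The energy functionals use their own
fourth-order centered stencils with the same symmetry closure, and the
Gaussian density is evaluated in the algebraically equivalent Hessian
form (via ∇²|∇ϕ|²/2 = ‖H‖² + ∇ϕ·∇∇²ϕ, H = Hess ϕ):

    ΨG = 2|H∇ϕ|² − 2(∇ϕᵀH∇ϕ) tr H + |∇ϕ|²[(tr H)² − ‖H‖²].

This choice is load-bearing.  ΨG is a difference of terms of size
O(ϵ⁻⁵κ) whose sum is only O(ϵ⁻⁴κ²) (κ a curvature); evaluating it by
composing first/second-order operator applications (gradient of |∇ϕ|²,
Laplacian of |∇ϕ|², …) leaves O(h²) truncation residues of the *large*
terms that grow linearly with vesicle size relative to the signal — at
λ = 0.02 and h = 2ϵ/3 the sphere's EG comes out at −6.5·4πkG instead of
+4πkG.  The Hessian form cancels the large terms identically at the
discrete level (it is stationary with respect to Hessian perturbations
about the planar profile), leaving a pure interface-resolution error:
EG(sphere) is then within 1.7% of 4πkG at h = 2ϵ/3 and 0.6% at h = ϵ/2,
independent of λ, and a relaxed torus quantizes to |EG/4πkG| < 10⁻⁴.

All functional gradients are exact reverse-mode derivatives of the
discretized functionals through the sparse operator matrices; the
directional-derivative identity ⟨∂F/∂ϕ, δ⟩ = d/dh F(ϕ+hδ) holds to
roundoff and is enforced by tests for every functional.  The continuum
variational derivative is the nodal gradient divided by the quadrature
weight.

## Constrained relaxation

Equilibrium shapes minimize E at fixed A = A0 and V = V0 via an
augmented Lagrangian L = E + μ_A ĉ_A + μ_V ĉ_V + (p/2)(ĉ_A² + ĉ_V²)
with relative violations ĉ, first-order multiplier updates μ ← μ + p ĉ
and penalty doubling on stagnation (defaults: p = 200·8πk, tolerances
10⁻³ relative, residual 10⁻⁴·8πk/ϵ³ on the constraint-projected
variational derivative sup-norm).

The inner stage is L-BFGS in a preconditioned variable
u = √(2c_EB)·√W·(w′(ϕ) + σ − ∇²)ϕ, where c_EB = 3kϵ/4√2,
w′(ϕ) = (3ϕ²−1)/ϵ² is the linearized double-well reaction, W the
quadrature weights and σ = 10⁻³/ϵ² a small invertibility shift.  The
bending Hessian is ≈ 2c_EB (∇²−w′)ᵀW(∇²−w′), so this change of variables
flattens the spectrum across interface-profile modes (curvature ~ k/ϵ⁴)
and shape modes (curvature ~ kϵ/Dve⁴) — a raw L² gradient flow would
need ~Dve⁴/(kϵ²·dt) steps to move shapes, which is why a time-stepping
scheme (even linearly implicit) was rejected for desk-scale work; an
explicit reference kernel (`augmented_step`) with its dt ≤ h⁴/(64c_EB)
stability bound is retained for verification.  The preconditioner is
refactorized (sparse LU) at every outer iteration.  Typical cost: a
sphere at λ = 0.025 converges in ~140 inner iterations (< 1 s); the
oblate at λ = 0.01 on a 109×96 grid in ~7000 iterations (≈ 1 min),
reaching E/8πk = 1.176, EB/8πk = 1.673, EG/8πk = −0.497 against the
sharp-interface discocyte values 1.17 / 1.67 / −0.5.

## String method

Minimal energy paths are computed with the simplified string method:
alternate a few inner constrained-descent iterations per interior image
(same machinery as above, with per-image multipliers and a trust region
of 0.2× the image spacing per cycle; multiplier updates are skipped on
trust-capped steps to avoid limit cycles) with redistribution of the
images to equal arc length in the 2πr-weighted L² norm of ϕ.

Two numerical choices here deviate from the most naive implementation
and are essential with kG < 0:

* **Interpolation happens in the signed-distance representation.**  Both
  the initial path and every reparametrization blend images through
  d = √2ϵ·atanh(ϕ) and map back with tanh.  Chords in ϕ space between
  displaced tanh profiles are smeared two-interface states: they raised a
  pure-translation path's energy by ~0.7·8πk per cycle, while d-space
  blends keep it flat to < 10⁻³·8πk.  A topology change appears in this
  representation as a neck radius passing smoothly through zero, so the
  initial oblate→torus guess is already a physical piercing sequence
  with a smooth energy profile.
* **A physical-state guard with healing.**  Off the interface manifold
  the discrete EG is unbounded below when kG < 0 (grid-scale structure
  makes ΨG ~ h⁻⁶ beat ΨB² ~ h⁻⁴), so unconstrained descent on rough
  states can run away.  Candidate steps whose energy falls below the
  endpoint floor minus 8πk, or whose EG/4πkG leaves [−1.5, 2.5] (the
  physically reachable genus/component range here), are rejected; any
  image pushed off the manifold by redistribution is re-seeded as a
  d-space blend of its nearest physical neighbors.

Constraint projection of interpolated images (a 2×2 Newton step along
the area/volume gradient directions) is available but off by default for
distance interpolation: d-space blends already sit within ~1% of the
targets, and the projection directions distort the interface profile,
which the per-image augmented Lagrangian then has to repair.

**Scale continuation.**  d-space blends are only good when the two
endpoint surfaces are within a few ϵ of each other along most of the
path.  For large vesicles (λ ≲ 0.012 here) the oblate and torus surfaces
are tens of ϵ apart, the blend gradients misalign, interface widths come
out wrong, and the initial string starts with EB up to ~28·8πk —
unrecoverable territory.  The remedy is continuation in vesicle size:
converge the string at λ ≈ 0.018 (where blends are well conditioned and
cycles are cheap), rescale every image geometrically in the distance
representation, d_new(x) = s·d_old(x/s) with cubic interpolation
(`rescale_field`/`rescale_path`) — the shape grows by s while the
profile stays an ϵ-width tanh — substitute freshly relaxed endpoint
states at the new scale, and polish.  Gradient-renormalized blends and
Euclidean-distance-transform redistancing were both tried and perform
far worse (profile destruction and pixelation artifacts respectively).

Convergence is declared on either vanishing net image displacement per
cycle or stationarity of the energy profile E(α) (default
2×10⁻⁴·8πk per image over 25 cycles): near-neutral directions let images
creep tangentially long after the barriers are stationary.

Saddles are reported at image resolution; as in the source analysis, the
steepest stretch is re-run as a denser sub-string (`refine_segment`)
rather than using climbing images.  The α ≈ 0.66 saddle / α = 0.67
hemifusion-minimum pair of the piercing transition is separated by only
Δα ≈ 0.01, so it is *invisible* to a uniform 30-image string and only
appears in the refined segment.

### Problem sizes and what they resolve

Desk-scale runs in the tests and the reproduction script use λ = 0.01
(Dve = 100ϵ ≈ 83 nm, grids ≈ 110×100) for relaxed-shape energies, and
scaled-down strings with N = 18–30 images at λ = 0.01–0.018 for path
structure.  These sizes were chosen as the smallest at which the
sharp-interface energies are inside the tolerances quoted above; barrier
heights are λ-sensitive (at λ = 0.018 the Clifford torus hole is ≈ 5.5ϵ,
comparable to the membrane thickness, and the backward fission barrier
nearly vanishes), so quantitative barrier comparisons are made at
λ ≈ 0.01 and qualitative structure at smaller sizes.

Barrier accuracy is dominated by string convergence, not by the energy
evaluation: the oblate→torus continuation pipeline with a generous cycle
budget (hundreds of polish cycles and a 30-image refinement, tens of
minutes) reaches forward / backward barriers of 0.561 / 0.185 ·8πk and a
hemifusion escape barrier of ≈ 0.31·8πk against the sharp-interface
reference values ≈ 0.57 / 0.17 / 0.256, while the short-budget
configuration used inside the test suite (≈ 10 minutes end to end)
stops around 0.46–0.52 / 0.08–0.14 with the narrow saddle–minimum pair
of the hemifusion region not yet resolved.  The corresponding test
tolerances are therefore expected to fail in a time-boxed run; the
kG-ordering of the forward barrier is robust already at short budgets,
whereas the ordering of the (ripple-scale) hemifusion well depths is
not.

## Lateral stress profile

For the flat membrane the bending energy can be rewritten in the
Gompper–Zschocke form ∫[c(∇²ϕ)² + g(ϕ)|∇ϕ|² + f(ϕ)]dV with
c = 3kϵ/4√2, g = 3k(3ϕ²−1+2√2mϵϕ)/2√2ϵ, f = 3k(ϕ²−1)²(ϕ+√2ϵm)²/4√2ϵ³,
giving the closed-form lateral stress on the planar profile

    sb(z) = 2g(ϕ0)ϕ0′²/ϵ² + 4cϕ0″²/ϵ⁴,
    sG(z) = 35kG(12ϕ0′²ϕ0″² + 4ϕ0′³ϕ0‴)/(16√2ϵ³),

(primes: derivatives in z/ϵ).  Exact consequences implemented and
tested: s(0) = 0 iff kG/k = −24/35 (returned as an exact fraction);
∫z·s dz = −2km; ∫z²·s dz = kG + 2k; sG has vanishing zeroth/first
moments and second moment exactly kG.  The zeroth moment ∫s dz = 2km²
(spontaneous tension) is a subtlety: the symmetric-membrane formula for
sb integrates to zero for *any* m because its m-dependence is odd in z.
The tension is an O(m²) quantity equal to the excess bending energy per
unit area of the flat frustrated membrane, (3kϵ/4√2)∫ΨB[ϕ0]²dz = 2km²
exactly; `stress_moments` integrates that density alongside s(z) for the
zeroth moment and documents that its O(m²ϵ²) second moment lies beyond
the order at which kG + 2k is defined.  Moments use adaptive quadrature
truncated at |z| = 12ϵ (tails decay like e^(−√2z/ϵ); truncation error
~e⁻¹⁷).  Extrema are located by ϵ/200 sampling plus parabolic
refinement; with k = 20 kBT, kG = −2k, ϵ = 5/6 nm the profile has a
2,888 bar maximum and −1,527 bar minima.

## What the generator does and does not emulate

Fixtures (sphere, two spheres, oblate spheroid, Clifford torus) are tanh
profiles of exact signed distances (point-to-ellipse distance by Newton
iteration for the spheroid); they represent ideal, noise-free membrane
geometries.  Passing tests therefore validate the elastic model and its
numerics, not robustness to experimental realities: there are no thermal
fluctuations, no hydrodynamics (the relaxation flow is a minimization
device, not dynamics), no hydration repulsion or other molecular detail
(the approach plateau of two vesicles is exactly neutral here, whereas
real membranes pay a hydration cost), no leaflet-resolved composition,
and strict axisymmetry (non-axisymmetric escape paths, if any, are
outside the search space).

## Known limitations

* Barrier heights from scaled-down strings are systematically
  λ-dependent; quantitative agreement with the sharp-interface values
  requires λ ≲ 0.01 *and* segment refinement near the saddle, which is
  the expensive part of the pipeline (tens of minutes at desk scale).
* The reduced volume of an unrelaxed tanh fixture is biased by
  O(λ²·profile) terms (~0.7% at λ = 0.02); constraint targets should be
  taken from analytic geometry (as the reproduction script does), not
  from the fixture, when exact targets matter.
* The heuristic physical-state guard bounds EG/4πkG to [−1.5, 2.5],
  which is correct for ≤ 2 vesicles of genus ≤ 1; exotic multi-component
  or high-genus studies would need the bound widened.
* `membrane_separation` measures the gap between marching-squares
  isolines, so its resolution is limited by the grid spacing (~0.1ϵ in
  practice after subpixel interpolation).
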