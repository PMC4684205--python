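# Methods

`plesioswim` simulates straight swimming of a neutrally buoyant,
four-flippered marine reptile — a 3.35 m plesiosaurian of generalized
proportions — by coupling an articulated rigid-body model to a grid-based
incompressible Euler fluid, and searches its periodic limb-stroke space
with CMA-ES. This note records the model, its numerical choices, and what
the shipped tests do and do not demonstrate.

## Body model

The body is five rigid links. The torso (head + neck + trunk + tail) is a
single link: a sturdy trunk is a prerequisite for purely paraxial
locomotion, and keeping the neck and tail immobile isolates the
contribution of the limbs. Each flipper is one rigid link attached at a
single ball joint at the anatomically appropriate girdle position — the
real animals had exactly one mobile joint per limb, between the propodial
and the girdle.

Meshes are generated procedurally: the torso as a loft of super-elliptical
cross sections (exponent 2.3) through a width/height profile table
calibrated to the published overall dimensions (3.35 m length, broad
pectoral/pelvic trunk, moderate neck, dorsally expanded tail fin); the
flippers as cambered NACA-like hydrofoil plates (16% thickness, 4% ventral
camber) with a posterior soft-tissue trailing-edge extension and rounded
tips. Every feature respects a 67 mm minimum thickness, the smallest
feature the default fluid grid can sense; thinner anatomy (flipper
trailing edges) is thickened to that floor. The exact cross-section tables
of any individual fossil are not reproduced; what matters downstream is
the overall dimensions, flipper area and aspect, and pivot placement.
A "bulky" variant scales the cross-sectional *area* around the limb
girdles by `muscle_bulk_factor` (1.5 = +50% soft tissue) via Gaussian
bumps in the profile; flipper planforms are untouched.

Mass properties come from the watertight meshes at uniform density
1000 kg/m³ (identical to the fluid: the animal is assumed neutrally
buoyant, ignoring lungs and gastroliths). Coordinates: x = initial heading
(anterior), y = lateral (left positive), z = up.

## Stroke model

Each joint decomposes into dorsoventral (dv), anteroposterior (ap) and
pronation/supination (rot) components. Every DOF follows a sinusoid
described by (min, max, phase); all sinusoids share 0.5 Hz. Two
modifications: a per-DOF time asymmetry `a` (the half-cycle toward the
power extreme — ventral, posterior, pronated — takes `(1-a)` of the
period) and a per-pair rotation hold (the rotation signal is flat for
`h/2` at *each* extreme, with the sweeps compressed into the remainder).
The hold is split across both extremes because the blade pitch is held
through both the downstroke and the upstroke, flipping quickly at the
top and bottom; published stroke descriptions are ambiguous on whether
one or both extremes were held, and the symmetric choice makes the
signal's two sweeps equivalent. Left/right limbs are synchronous (straight
swimming); fore and hind pairs are independent. Total: 18 sinusoid values
+ 6 asymmetries + 2 holds = 26 free parameters (13 for single-pair
experiments).

Joint-range presets (narrow/medium/wide) ship as editable JSON. The
dv/ap endpoints were back-derived from the published optimized ranges and
their printed percent-of-available-range values; the rotation range is
the same in every preset (30° supination to 45° pronation; positive
angles denote pronation). Neutral poses: forelimb (−15° dv, −16° ap),
hindlimb (−30°, −27°). The "fully abducted" start pose is the preset's
maximum dorsal elevation (no published number exists).

The shipped *reference strokes* are built from the published optimized
medium-range parameters (ranges, asymmetries, holds). Phases are not
published; they follow the underwater-flight convention (dv starts at the
dorsal maximum so the motion opens with a downstroke; the pronation
plateau covers the downstroke), with the rotation phase set once by a
small grid search over candidate phases maximizing cycle-2 travel of the
reference stroke — a one-time calibration of otherwise-unspecified
parameters, applied identically to both limb pairs.

## Articulated dynamics

Equations of motion in generalized coordinates, `M(q) q̈ + C(q, q̇) =
τ_int + τ_ext`, with 18 DOF: 6 floating-base (orientation stored as a
unit quaternion; the three rotational velocity coordinates are the
world-frame angular velocity, so pitch beyond ±90° is unproblematic) plus
4×3 joint angles. `M` is assembled from link COM Jacobians and
world-frame inertia tensors; `C` uses Jacobian time-derivatives evaluated
by central differencing along the state flow (step 1e-6 s) plus the
gyroscopic term — at the fluid time step this is as accurate as the
integrator and avoids a long analytic derivation.

Joint tracking uses the stable-PD law: the proportional term is evaluated
at the predicted next-step angle, `−k_p(θ + Δt θ̇ − θ̄)`, and the damping
term's implicit part `−k_d Δt θ̈` is folded into the acceleration solve
(`(M + Δt K_d) q̈ = …`). This matters: the flipper's long-axis rotation
inertia is small (~0.05 kg m²), so at the fluid step Δt = 0.01 s the
explicit damping law diverges at any useful gain. Default gains
k_p = 6000 N·m/rad, k_d = 300 N·m·s/rad track the reference strokes to
under 1° RMS in vacuum and a few degrees in water; both are config.
Integration is semi-implicit Euler at the fluid step, matching the
coupling's staging.

## Fluid

Incompressible Euler (water's viscosity is negligible at this scale) on a
staggered MAC grid: face-normal velocities, cell-centered pressure.
Advection is BFECC built from clamped trilinear semi-Lagrangian sweeps
(forward, backward, error-halved correction, forward; result clamped to
the local sample bounds of the original field so no new extrema appear),
sub-stepped when the CFL number exceeds 0.9. Gravity is explicit Euler.
The domain is 6.6 × 5.28 × 3.96 m with no-penetration side/bottom walls
and a p = 0 free surface at the top plane, discretized with the half-cell
ghost (factor-2 Dirichlet) so hydrostatic pressure is reproduced to
round-off. The swimmer starts ~1.8 m below the surface and ~1.2 m above
the bottom, deep enough that boundary effects are small over two cycles.

The pressure system is solved by conjugate gradients preconditioned with
a modified incomplete Cholesky MIC(0) factorization of the constant
all-fluid Laplacian (built once per grid and time step; the coupled
matrix differs from it only near the body). Cells without pressure
equations keep decoupled diagonal rows scaled to the stencil magnitude so
the preconditioned spectrum stays clustered; typical solves converge in
40–80 iterations at relative tolerance 1e-8.

## Two-way coupling

Each step: (1) advect + gravity for the fluid, stable-PD + gravity for
the body, each ignoring pressure; (2) re-voxelize the posed body onto the
grid, assemble one SPD linear system over cell pressures, solve, then
project the fluid (`u = u* − Δt∇p/ρ`) and apply the pressure impulse to
the body (`Δq̇ = Δt M⁻¹ τ`).

Voxelization labels a cell solid iff its center is inside any posed link
mesh (ray-casting parity with a scanline sharing one axial ray per (y,z)
column of the sub-lattice; a deterministic sub-cell z-jitter of the
lattice avoids degenerate hits, and the lattice is kept exactly
mirror-symmetric in y so voxelized left/right limbs match to the 1/27
quantum). Fluid volume fractions use 3×3×3 sub-cell centers (1/27
precision); fractions below 0.01 are clamped to solid for conditioning.

The pressure force on the body is the surface integral
`τ = Σ_i v_i Δx² J_iᵀ p_i n_i` over coupled faces (fluid-labelled cell
next to solid-labelled cell), where `v_i` and `p_i` are the fluid volume
fraction and pressure of the interface fluid cell and `n` the
grid-aligned face normal (mesh normals appear only in visualization).
Substituting the body's response `q̈ = M_eff⁻¹ τ` (the stable-PD effective
matrix, factorized exactly per step — 18×18) into the fraction-weighted
divergence constraint adds the symmetric PSD block
`(Δt/Δx³) H M_eff⁻¹ Hᵀ` to the Poisson matrix; the same `H` produces the
force afterwards, giving discrete action–reaction. The convective
interface term `J̇q̇` enters the right-hand side, evaluated by central
differencing of material-point velocities along the state flow. The
matrix-free operator is solved with the same MIC(0)-preconditioned CG.
With no solid cells the system is entry-wise the pure-fluid Poisson
system; with the body's mass sent to infinity it reduces to a
fixed-obstacle projection.

Gravity on the solid is discretized *through the interface operator*:
the generalized weight is `−Hᵀ p_h`, the hydrostatic field mapped through
the same face data that integrates pressure. For a neutrally buoyant body
this makes the hydrostatic state an exact discrete equilibrium (the solve
returns `p_h` and every velocity stays zero to solver tolerance), so a
resting body does not creep; the magnitude converges to `m g` with
resolution (it is the weight of the voxelized displaced volume). The
generic `gravity_force` (per-link `m g` through the COM Jacobians)
remains available for dry dynamics.

After the solve, the body's velocities are corrected by the pressure
impulse (rather than re-stepping the articulated dynamics) and positions
advance with the corrected velocities.

Validation physics worth noting: an impulsively started sphere keeps 2/3
of its speed after one coupled solve — the analytic added-mass result
(m_added = m/2) — and the flow around it matches the potential dipole on
a shell one cell out to ~10%, with the 3×3×3 fractions strictly closer
than binary voxelization.

## Quality function and experiments

A simulation starts from rest (water and body), active limbs fully
abducted, inactive limbs locked at neutral, and runs ≥ 2 cycles. Quality
is evaluated over the *second* cycle only (the first covers the start-up
transient): `q = d_forward − w_dir‖d_perp‖ − w_orient|Δorientation|`,
with `d_forward` the COM displacement projected on the initial heading,
both perpendicular components (lateral and vertical) penalized, and the
orientation deviation the geodesic angle between the cycle's start and
end base orientations. The weights (w_dir = 1 m/m, w_orient = 0.5 m/rad)
are config; comparisons in the tests use the deviation metrics directly
so they are weight-independent. Frame invariance holds by construction.

CMA-ES (our implementation: standard (μ/μ_w, λ) with evolution paths,
rank-1 + rank-μ covariance update, CSA step-size control, and active
negative-weight recombination) searches the 26-D (or 13-D) box in
box-normalized coordinates, initial mean at mid-range angles / 0.25
phases / symmetric timing / zero hold, initial σ = 0.3 of each
coordinate's width. Bound handling is resampling (up to 50 draws), then
clipping with a quadratic quality penalty so covariance updates stay
unbiased near bounds. Defaults follow the study design: 31 samples per
iteration, ~70 iterations; evaluations are side-effect-free and can run
on parallel workers with bit-identical results.

## Problem sizes used by the shipped tests

Full-scale runs (100×80×60 grid at Δx = 0.066 m, ~1 h per simulation;
cluster-scale CMA with thousands of simulations) reproduce the published
absolute speeds but are far outside a test suite; the package exposes
them as configuration (`grid="paper"`, default OptConfig). The shipped
tests and the acceptance script use:

- desk grid 50×40×30 (Δx = 0.132 m), Δt = 0.01 s, two cycles per
  simulation (~400 coupled steps, one to two minutes each) for the
  swimming comparisons;
- 25×20×15 at Δt = 0.02 s for cheap orchestration checks;
- 32³–48³ boxes for the sphere statics;
- the drag-paddle surrogate for optimizer end-to-end runs.

At the desk grid the flippers are only one to three cells thick, so
absolute thrust is strongly under-resolved: distances per cycle are
roughly a third of the full-scale values and lift-based (flight-stroke)
propulsion loses most of its advantage over drag-based paddling. Passing
desk-scale tests therefore demonstrates the correctness of the coupled
machinery and the direction of physical effects (thrust exists, symmetric
strokes swim straight, added drag slows the bulky body), not the
published absolute performance or the full-scale forelimb/hindlimb
contrast: lift-based flight propulsion, the mechanism that favors the
forelimbs at full resolution, is unresolved on 1–3-cell-thick hydrofoils,
and both limb pairs reduce to comparable drag-paddling.  The acceptance
script measures the desk-scale fore/hind distance ratio directly so the
gap is quantified rather than hidden.

## Known limitations

- Rigid flippers: real limbs flexed and twisted along their length,
  which increases tip range of motion and reduces drag; modeling this
  needs a deformable-body simulator and a different coupling.
- No viscosity: boundary layers and skin friction are absent; numerical
  viscosity (advection diffusion, voxelization drag) partially mimics
  form drag but is resolution-dependent.
- Free-surface plane is fixed (no waves) and walls reflect pressure; the
  swimmer should stay away from both.
- Neutral buoyancy is uniform; lungs/gastroliths and trim control are
  out of scope.
- The optimizer finds good local optima; distinct runs differ slightly
  (the published experiments observed the same).
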