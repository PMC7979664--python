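# Methods

This note records the model equations as implemented, the numerical choices
behind them, what the synthetic inputs emulate, and the known limitations.

## Elastic model

Displacements u = y − x map reference to deformed coordinates; the
deformation gradient is F = ∂u/∂x + I.  With C = FᵀF the implementation
uses the invariants J = det F, T_C = tr C, T_C² = tr(C²), and the reduced
combinations I = T_C J^(−2/3), K = ½(T_C² − T_C²-trace) J^(−4/3) — computed
from traces, never from an eigendecomposition.  The Mooney–Rivlin energy
density is

U = (μ₁/2)(I − 3) + (μ₂/2)(K − 3) + (κ/2)(J − 1)²,

with μ₁ = wμ, μ₂ = (1−w)μ, μ = E/(2(1+ν)), κ = E/(3(1−2ν)).  Setting w = 1
recovers the compressible neo-Hookean law.  ν = 0.5 is rejected (κ
diverges); the package default is ν = 0.48, near-incompressible.

A direction-of-effect note: under uniaxial *extension* the I-term dominates
(I − 3 grows like λ², K − 3 like λ), so decreasing w softens the response;
under uniaxial *compression* (equivalently equibiaxial extension) K grows
faster (1/λ² versus 1/λ) and decreasing w stiffens it.  This is the
strain-hardening behaviour relevant to plate compression, and is asserted
in the tests in its compression form.

## Discretization and force assembly

Each tetrahedron carries linear (P1) shape functions with the 4th stored
vertex as local origin, so the reference Jacobian has columns
J_col,k = x^k − x^4, B = J⁻¹ is precomputed once, and
F = A·B + I with A_col,k = u^k − u^4 constant per element.  Nodal forces are
the exact analytic derivative f_i^α = −V₀ ∂U/∂u_i^α via the chain rule
through (T_C, T_C², J); the individual partials are implemented exactly in
the literal form (∂T_C/∂F = 2F, ∂J/∂F_il = J F⁻¹_li as the cofactor matrix,
∂T_C²/∂F = 4FC, ...), with no algebraic re-simplification, and are verified
against an independent central-difference gradient of the total energy
(relative agreement ≤ 1e-6 on random smooth states; the oracle uses step
1e-7·R).  Element inversion (J ≤ 0) is a hard error naming the element, not
an energy regularization.  Assembly order is fixed (ascending element
index), so results are bitwise reproducible.

## Mesh generation

The ball mesh uses a trimesh icosphere surface (subdivision 3 by default,
642 surface vertices), interior vertices on concentric shells (Fibonacci
points, counts proportional to shell area, spacing = surface edge length /
1.4) plus the center, tetrahedralized with scipy's 3D Delaunay.  Interior
points carry a small seeded jitter (σ = 5% of the edge length) to break the
cospherical degeneracies Delaunay handles poorly; if any element volume
falls below 1e-6 of the mean, generation retries with a fresh jitter.
Defaults produce 2263 vertices and ~12000 tetrahedra; the boundary triangles
are extracted from the tetrahedra themselves (faces belonging to exactly one
element, oriented away from the opposite vertex), which makes the
divergence-theorem surface volume agree with the summed element volumes to
round-off.  Generation is deterministic for a fixed seed.

Delaunay meshes of spherical point clouds contain some high-aspect boundary
elements (max ‖B‖ ≈ 50/R at default resolution).  These are harmless for
smooth deformation fields but mean that i.i.d. per-vertex noise is not a
valid "small" displacement field; the random states used in verification are
therefore smooth (affine + long-wavelength sinusoid).

## Quasi-static contact experiments

Plate compression and sphere indentation run in dimensionless units (length
R, stress E), which makes the recorded force exactly linear in E at fixed
(ν, w, deformation) — a property the (E, w) fitter exploits by simulating
once per w and rescaling.  Plates/probe are rigid; a vertex penetrating by δ
feels a linear penalty force k_c δ along the inward normal, k_c = 100·E·R by
default (a numerical knob: doubling it changes curves by < 2% RMS).  The
moving boundary advances in increments of 0.5% of the undeformed cell height
(1% for the deep-compression and fitting studies), and after each increment
the vertices are relaxed by overdamped pseudo-dynamics with adaptive step
size (FIRE: velocity mixing toward the force direction, step growth on
downhill progress, half-step retraction and velocity reset on uphill power,
step reduction and state revert on element inversion).  Relaxation stops
when the maximum residual vertex force falls below residual_tol·E·R²
(default 1e-4), with an iteration cap of 20000 per increment; exceeding the
cap is an error, never silently accepted.  The recorded force is the total
normal penalty force transmitted to the moving plate/probe.  Deformation is
boundary travel divided by the undeformed cell height.

Hertz references: sphere-between-plates uses the two-contact form
F = (4/3)(E/(1−ν²))√R (d/2)^{3/2}; probe indentation solves the series
arrangement of a probe contact (effective radius (1/R + 1/R_probe)⁻¹) and a
substrate contact carrying equal force.

Known systematic: at the default resolution the simulated small-deformation
force lies ~20–35% above the two-contact Hertz form and converges toward it
only under uniform mesh refinement (~1.15 at eight times the element
count).  The overshoot is the stiffness of linear tetrahedra — aggravated by
near-incompressibility (volumetric locking at ν = 0.48) — plus the physical
finite-sphere deviation from half-space contact theory at finite
deformation; the energy density itself reproduces the linear-elastic
quadratic form analytically to < 1%.  Conclusions that depend on the
absolute force scale at the default resolution inherit this bias; curve
*shapes*, parameter ratios and the flow results do not.

## Shape metrics

The inertia tensor Θ_ij = Σ_l V_l (r·r δ_ij − r_i r_j) sums current element
volumes at element centroids r relative to the volume-weighted center of
mass (uniform density).  For a uniform solid ellipsoid the eigenvalues
θ₁ ≥ θ₂ ≥ θ₃ give *squared* semi-axes via (5/2M)(−θ₁+θ₂+θ₃) etc. — the
implementation takes the positive square root of each combination, the
choice fixed by the sphere round-trip a = R and by dimensional analysis.
Negative combinations raise a "non-ellipsoidal inertia" error; exact zeros
pass as the degenerate boundary.  D = (a₃−a₁)/(a₃+a₁).  Net strain uses the
exact maximum vertex-pair distance (candidates restricted to convex-hull
vertices) against d_ref = 2R.  A net strain of 1 corresponds to a
configuration stretched to twice its reference diameter; the metrics report
both Δε and the stretch ratio d_max/d_ref, since "stretched to p% of its
size" is ambiguous between the two conventions.

## Lattice-Boltzmann / immersed-boundary flow

D3Q19 BGK with Guo forcing.  Fluid nodes sit at (i+½, j+½, k+½); the two
x–z walls are realized by half-way bounce-back with a moving-wall momentum
correction and therefore lie exactly in the planes y = 0 and y = H = N_y Δx,
moving at ∓u_wall = ∓½Hγ̇ (+ an optional common offset for Galilean checks).
With this convention the solver reproduces the analytic Couette profile at
the node centers to round-off from a sheared start and to < 1% of u_wall
within a momentum-diffusion time from rest, and body-force Poiseuille flow
to < 0.2%.

The simulation runs in lattice units (Δx = Δt = ϱ = 1).  The lattice shear
rate is chosen for numerical quality, not to match the physical clock:
u_wall = 0.04 keeps the Mach number low, and τ = 1 (ν_lat = 1/6) keeps the
particle-scale Reynolds number γ̇ R²/ν ≈ 0.1–0.3, an acceptable stand-in for
the Stokes regime of the physical parameters (η = 1 mPa·s, γ̇ = 4 s⁻¹,
ϱ = 10³ kg/m³).  What is matched exactly is the capillary number
Ca = ηγ̇/μ, which sets the cell's lattice shear modulus; each run returns a
conversion record (Δx, Δt, mass scale, μ in both unit systems) mapping
lattice to physical units.

Coupling is the classical immersed-boundary cycle with a 4-point Peskin
kernel: interpolate fluid velocity to all mesh vertices, advect them with
explicit Euler, spread elastic (+ repulsion) vertex forces back to the
lattice.  The kernel stencil clamps at the walls; interior fluid stress is
*not* subtracted, so the cell interior effectively carries the fluid
viscosity (viscosity ratio λ = 1; a λ ≠ 1 contrast method is out of scope).
Multi-cell runs add a short-range penalty repulsion (range 0.1R) between
surface vertices of different cells and against the walls, with seeded
rejection-sampled non-overlapping initial placements; reported volume
fractions are geometric (Σ cell volume / box volume).

Steady state is detected as a relative change of the cell-averaged Taylor
parameter below 1e-3 over one shear time, never before the transient
(default: first 5 shear times) plus one shear time has passed; reported
mean D averages cells and the post-transient samples.

## Problem sizes used in the distributed checks

Verification runs use the coarse mesh (subdivision 2, ~360 vertices) for
gradient-level checks, the default mesh (2263 vertices) for the Hertz,
strain-hardening and metric checks, and a coarse flow configuration (cell
radius 4 Δx in an 8×8×4 R box, three capillary numbers 0.05/0.1/0.2, 8
shear times) for the shear physics; these sizes were chosen so the full
suite runs on a laptop-class single core.  Production-scale settings (cell
radius 5–8 Δx, 10×15×5 R single-cell box, 5×8×4 R multi-cell box per the
study geometry) are the CLI defaults.

## What the synthetic data emulate — and what they do not

The generators produce: ideal tetrahedral ball meshes; prescribed affine
deformations (exactly representable by P1 elements, hence machine-precision
oracles); smooth random displacement fields; and forward-model
force–deformation curves with 2% multiplicative Gaussian noise emulating
instrument noise after contact-point and stiffness calibration.  They do not
emulate: cell-to-cell variability of E and w, adhesion or friction against
the plates, suction-pressure holding forces, cantilever compliance and
contact-point detection errors, viscoelastic (rate-dependent) response, or
nucleus/cortex heterogeneity.  Passing the recovery tests therefore shows
the inverse problem is well-posed for the forward model itself, not that
instrument systematics are handled.

## Known limitations

* Linear tetrahedra are stiff near ν = 0.5 (see the Hertz systematic above);
  no F-bar/mixed formulation is provided because the force assembly is
  deliberately the literal analytic gradient of the stated energy.
* The contact is frictionless and purely repulsive — no adhesion hysteresis.
* The flow solver supports plane Couette (and body-force Poiseuille)
  geometry only; one relaxation time (BGK); no viscosity contrast.
* Tank-treading is diagnosed qualitatively (tagged-vertex phase angle), not
  quantified as a frequency.
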