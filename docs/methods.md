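# Methods

This note documents the models, numerics and design choices behind
`leukotransit`: a 2D fluid–structure simulator of a leukocyte squeezing
through a sub-cellular vascular pore, and the backpropagation-network
surrogates trained on its output.

## Physical model

A single immune cell is idealized as a closed, linearly elastic membrane
(thickness h = 0.4 µm, elastic modulus E = 100 Pa by default, admissible
50–500 Pa, Poisson ratio ν = 0.25) enclosing cytosol with the same
properties as the surrounding plasma: Newtonian, dynamic viscosity
µ = 8×10⁻⁴ Pa·s, density ρ = 1000 kg/m³.  The cell (diameter d = 10 µm)
sits on the axis of a plane channel of width W = 20 µm containing a rigid
stenotic constriction — two blocks protruding from the walls, leaving a
gap of width AR·d, with rounded lips (radius 1 µm) and a streamwise extent
of 5 µm.  AR (pore width / cell diameter) below 1 means the pore is
narrower than the cell.

Flow is governed by the incompressible Navier–Stokes equations with the
membrane force as a body-force term.  The Reynolds number is defined as
Re = ρ·ū·W/µ with ū the mean inlet velocity of the *cell-free* channel;
the microvascular regime of interest is Re = 0.1–0.2, so the flow is
Stokes-like and laminar throughout.

**Pressure driving.** The channel is driven by a fixed pressure drop
Δp = 12µūL/W² (the plane-Poiseuille drop that sustains ū over the channel
length L = 80 µm), applied as pressure boundary values at the inlet and
outlet, rather than by a prescribed inflow.  This choice is physical and
consequential: with a prescribed flux, incompressibility forces any
elastic cell through any pore eventually, and permanent lodging
(impaction) cannot occur.  Under fixed pressure the cell can stall in the
pore when elastic resistance balances the drive.  The impaction detector
classifies a case as lodged when the centroid speed stays below
10⁻³·ū for 0.01 s while the membrane overlaps the pore; a run that ends
without either criterion is reported as `timeout-error`.  Under this
solver's conditions (2D planar geometry, the default driving above) the
study corner Re ≤ 0.14, AR ≤ 0.55 still transits slowly rather than
lodging; the canonical six-pair exclusion list therefore remains available
as an explicit configuration (`exclusion_mode: canonical`) alongside
outcome-detected exclusion.

## Fluid solver

Uniform staggered (MAC) grid: u on vertical faces, v on horizontal faces,
pressure at centers; spacing h = d/12 by default, d/8 in the desk-scale
profile.  Time integration is an incremental pressure-correction
(projection) scheme: explicit advection and explicit current-pressure
gradient, implicit (backward-Euler) viscosity, then a pressure-increment
Poisson solve with homogeneous Dirichlet values at the open boundaries and
homogeneous Neumann on walls.  At steady state the scheme satisfies the
discrete Stokes balance exactly; the cell-free channel reproduces the
parabolic profile to machine precision (the no-slip walls use a quadratic
ghost closure that is exact for parabolas).  All operators are assembled
once per run and LU-factorized, so a step costs three sparse triangular
solves; the discrete divergence after projection is at the direct-solver
roundoff level (~10⁻¹⁶ dimensionless, asserted < 10⁻⁸).

**Constriction representation.** Cells deep inside the blocks are removed
from the unknowns (hard no-slip).  Cells cut by the block surface carry a
Brinkman (volume-penalty) drag χ/ε·u with a Carman–Kozeny-style
coefficient, where the solid fraction χ follows the signed distance to
the rounded-rectangle blocks over a 1.5-cell ramp.  The penalty tier gives
the wall position sub-cell resolution: the pore conductance — and hence
every learned observable — varies continuously with AR instead of jumping
in grid-spacing increments, which at the desk-scale resolution would
otherwise collapse the AR sweep onto two or three distinct geometries.
The penalty walls are slightly "soft" (a thin damped layer instead of a
sharp surface), which mildly widens the effective gap; this is a
regularization of geometry, not of the membrane mechanics.

**Time step.** dt is fixed per run at the minimum of an advective CFL
bound (CFL 0.25 against an estimated peak pore velocity) and an
overdamped-membrane stability bound µ/κ with κ the summed nodal stiffness
of the stretching, bending and area-penalty terms, times a safety factor
0.4.  Typical values are 3–4 µs at desk scale; a transit takes
10³–10⁴ steps.

## Membrane model and coupling

The membrane is a closed CCW polyline of Lagrangian markers (2 per grid
cell initially) with a circular unstressed reference.  Nodal forces are
exact gradients of a discrete energy:

* stretching: per-segment tension k_s(L/L₀ − 1) with
  k_s = E·h/(1 − ν²) ≈ 4.3×10⁻⁵ N/m at defaults; rest lengths are the
  reference-polygon chords so the discrete reference circle is exactly
  force-free;
* bending: a second-difference penalty scaled by
  k_b = E·h³/12(1 − ν²), measured relative to the reference curvature —
  a small regularizer (k_b/k_s·Δs² ≈ 4%) that suppresses sub-grid
  buckling;
* area: a weak global penalty of stiffness 2000 Pa on relative enclosed
  -area change, counteracting the slow volume leakage of regularized-delta
  interpolation.  Enclosed area drifts < 1% over every sweep transit
  (worst observed ≈ 0.8% at Re 0.2, AR 0.5).

Coupling uses the classical 4-point regularized delta kernel for force
spreading and velocity interpolation.  Because the energy is translation
invariant, total spread force is identically zero mod roundoff.

**Marker resampling.** Squeezing stretches the leading arc and crowds the
trailing arc.  When any deformed segment leaves [0.45, 1.9] grid cells,
markers are redistributed uniformly in deformed arc length (periodic cubic
spline, two passes); each marker carries its material angle on the
reference circle, interpolated along the curve, so the local elastic
strain survives resampling to interpolation accuracy.  Recorded spacing
stays within the kernel's reliable band [0.4, 2] grid cells.

## Observables

At a fixed output interval (0.2 ms at desk scale) the run records:

* displacement — centroid travel along the flow axis (non-decreasing for
  transits);
* R_max — maximum marker distance from the centroid (5 µm undeformed);
* V_y — centroid velocity along the flow axis (mean of interpolated
  marker velocities);
* F_l, F_d — lift and drag: the fluid traction σ·n integrated over a
  contour offset 2 grid cells outside the membrane, just past the delta
  kernel support where the stress field is one-sided.  Drag is the axial
  component over the whole contour; lift is the transverse component over
  the upper half-contour (the full-contour transverse force vanishes by
  symmetry).  On a rigid tethered cylinder this offset-contour integral
  agrees with the exact constraint-force sum to ≈ 4% at desk resolution
  (the raw on-membrane smeared traction would underestimate by ~2× because
  the interior-side contour integral vanishes).  In near-contact moments
  the contour samples the penalized wall layer, so the force reading there
  is a regularized approximation; it remains smooth and deterministic,
  which is what the surrogates require.

A transit ends when the trailing membrane point clears the pore exit
plane; the elapsed time is the transit time.  The initial standoff is
1.5·d upstream of the pore entrance (centroid), released from rest in
quiescent fluid.  Both endpoint and standoff are configuration-exposed.

## Surrogate networks

Feedforward nets with two hidden layers, tansig (tanh) hidden and purelin
output activations, written from first principles (forward pass, analytic
backpropagation, Jacobian).  Hidden sizes follow the combinatorial
capacity rule Σ_{n=0..M} C(I, n) > h: 15 nodes minimum for the 2-input
transit-time model (split 5 + 10) and 50 for the 3-input motion/force
models (split 20 + 30).

Training is Levenberg–Marquardt with adaptive damping (µ starts at 10⁻³,
×10 on rejection, ×0.1 on acceptance), the standard choice this class of
toolbox models denotes `trainlm`; plain full-batch gradient descent is
available for fidelity to the printed update rule and agrees with LM on
the analytic toy surface to held-out R² within 10⁻³.  Inputs and targets
are min–max normalized to [−1, 1] with constants fitted on the training
split only.  Stopping: training-MSE goal (10⁻⁵ for the time model, 10⁻³
for deformation, 10⁻¹⁰ velocity, 10⁻¹³ lift, 10⁻¹⁴ drag, with tightened
min-gradient floors for the force models), max 1000 epochs, validation
patience 6 (a toolbox convention; the patience is not stated in the
source literature), or exhausted damping.  The returned network carries
the best-validation-epoch weights.  The mean squared error is the
standard unweighted form; an equation in the source prints a weighted,
unsquared variant that is treated as a typo.

The per-sample split is 60/20/20 train/validation/test, seeded, with
floor-then-distribute rounding (115 cases → 69/23/23) and assignment keyed
to a canonical row ordering so arrival order cannot change the split.

## Study protocol and problem sizes

The full study grid is Re ∈ {0.10, 0.11, …, 0.20} × AR ∈ {0.50, 0.55, …,
0.95} (110 cases; a compatibility profile appends AR = 1.0 for the
121-case variant whose retained count after the canonical six-pair
exclusion is 115).  Ten off-grid (Re, AR) pairs are held out to test the
transit-time surrogate and four of them to test the motion/force
surrogates, always against freshly simulated truth.

The shipped desk-scale (`coarse-ci`) protocol — used by the test suite and
the acceptance script so the whole study runs on one CPU in minutes —
uses a 6×6 grid over the same box, grid spacing d/8, 0.2 ms trajectory
sampling (≈ 20–100 samples per case, ≈ 1500 motion rows), and three
training seeds per surrogate with the simulator output shared across seeds
(the solver is deterministic; seeds only enter splits and weight
initialization).  Reported accuracies are medians over the seeds.
Transit time at the baseline scenario changes by ~3% when the grid is
refined from d/12 to d/24, and the qualitative structure (monotone
decrease of transit time in both Re and AR, impaction-free transit over
the study box) is resolution-independent.

## What the surrogates do and do not demonstrate

The networks are trained and evaluated on this package's own simulator:
held-out R² near 1 demonstrates that small BPNNs interpolate the
simulator's smooth (Re, AR[, displacement]) response surfaces extremely
well, replacing minutes of simulation by microseconds of inference.  It
does not validate the simulator against laboratory measurements of real
leukocytes, and real cells (viscoelastic cortex, nucleus, adhesion
molecules, 3D geometry) will deviate from this 2D passive-membrane model.
The drag force is consistently the hardest of the four observables to
predict — its curve has the sharpest features at pore entry and exit —
mirroring the qualitative ordering reported for this class of models.

## Known limitations

* 2D planar geometry; no axisymmetric mode (drag laws differ between the
  two, and the source literature is ambiguous about which it used).
* Penalty walls leak slightly; effective pore conductance is accurate to
  the sub-cell ramp, not to machine precision.
* The lift/drag readings during near-contact sample the penalized wall
  layer (see Observables).
* No cell–wall adhesion, no contact mechanics beyond the resolved
  lubrication gap, no non-Newtonian plasma rheology.
* The impaction corner of the study grid does not reproduce under this
  solver's default driving; exclusion by detected outcome and by the
  canonical list are both supported.
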