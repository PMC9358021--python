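# Methods

## Scope and model structure

The package simulates the fluid side of a dynamic immune–tumor co-culture
device: a perfused chamber under a transwell insert, with NK-cell-sized
particles circulating in the flow and optionally crossing the insert
membrane upward under a chemotactic protrusion force. The wet-lab side of
such experiments (hydrogels, cytometry, cytotoxicity) is out of scope; the
only biological input is the set of physical cell parameters and, for
calibration, an observed extravasated fraction.

The computation has three stages, each importable on its own: a steady
incompressible laminar flow solve, Lagrangian particle tracing in the
frozen field, and ensemble analysis/calibration.

## Geometry reconstruction

The commercial device's internal drawings are not public. The reference
geometry is therefore a documented reconstruction, chosen once and exposed
to override in every config:

* circulation channels Ø 1.0 mm — picked so that the Poiseuille peak speed
  at the experimental 0.3 ml/min, u_max = 2Q/(πR²) = 1.27 cm/s, lands in
  the physiological capillary blood-flow range (~0–1.2 cm/s) the device
  is designed to reproduce;
* chamber Ø 16 mm × 1.5 mm fluid gap — hosts a standard 24-well insert
  (membrane Ø 6.5 mm) above the flow;
* circuit volume 1.5 ml (the chamber load); the part not meshed (≈1.2 ml)
  is the pump loop, represented as a plug-flow transit delay
  (V_loop/Q ≈ 239 s at 0.3 ml/min).

Dimensionality: tubes are solved axisymmetrically in (x, r); the device as
a 2-D longitudinal section (x, z) with unit depth. A 2-D section cannot
carry both the circular channel's peak speed and its volumetric rate; the
inlet parabola is scaled to the circular peak speed (the physically
meaningful scale behind the printed velocity range) and flux bookkeeping
uses the per-unit-depth rate. The ±15 % acceptance band on the peak speed
absorbs the planar approximation. Coordinates: z = 0 at the chamber floor,
membrane at z = 1.5 mm, gravity along −z; SI internally, bench units
(mm, ml/min, hours) at the config boundary.

## Flow solver

Staggered MAC grid (u on x-faces, w on z-faces, p in cells), uniform
spacing (default 50 µm, ≥8 cells across the narrowest passage enforced).
The steady Stokes problem is assembled in finite-volume flux form and
solved as one sparse saddle-point system (direct factorization), so
continuity holds to solver precision in every fluid cell — the measured
divergence and inlet/outlet flux mismatch are O(10⁻¹³) relative. Boundary
conditions: discrete parabolic inlet rescaled to carry the target flux
exactly; outlet pressure pinned to zero on the outlet plane via ghost-cell
mirroring (with zero-gradient outflow velocity); no-slip on all walls and
on the membrane, which is impermeable to the fluid (extravasation is a
cell process, not a fluid leak).

Two numerical choices matter for accuracy:

* tangential viscous fluxes at walls use a one-sided quadratic gradient
  (linear fallback at corners), which makes the scheme nodally exact for
  parabolic profiles — the straight-tube solution reproduces Poiseuille
  flow to the inlet-quadrature error (~0.3 % L∞ at 50 µm, 4× smaller per
  refinement);
* the convective term ρ(u·∇)u is off by default. At the device Reynolds
  number (≈6.4) enabling it (first-order upwind, lagged Picard iteration
  with under-relaxation 0.6) shifts the peak speed by ≈0.5 %; creeping
  flow keeps the solution exactly linear in Q, a property the tests check
  at 1 %.

Convergence contract: relative linear-solve (or Picard) residual below the
tolerance, default 10⁻⁶; non-convergence raises with the residual history
attached.

## Particle model

Spheres with r_p = 6 µm, ρ_p = 1080 kg/m³ in a ρ = 1000 kg/m³,
μ = 10⁻³ Pa·s medium. Forces: Stokes drag 6πμr_p(u_f − v_p), buoyant
weight m_p g(ρ_p − ρ)/ρ_p = 7.10×10⁻¹³ N (terminal settling speed
6.28 µm/s), and an optional protrusion force of constant magnitude along
+z, active only where the particle is beneath the membrane footprint (the
chemoattractant is sensed through the membrane; no diffusion PDE is
solved because no concentrations or diffusivities are available).

The relaxation time τ = 2ρ_p r_p²/(9μ) ≈ 8.6 µs is far below transport
timescales, so each step uses the exact exponential solution of the
linear-drag ODE with the fluid velocity frozen at the step start;
`overdamped` mode takes the τ→0 limit directly. The two agree to <10⁻⁹ m
over 10 s whenever dt ≥ 100τ. Default dt = 1 ms; long desk-scale runs use
the overdamped integrator at dt = 10–20 ms (step lengths ≤ 250 µm, small
against every geometric feature), which is the configuration used by the
analysis drivers and the long-duration tests.

Wall interaction is an elastic specular rebound at the analytic boundary
of the rectangle-union fluid region (exact segment–plane intersection, no
raster tunneling); speed is preserved to machine precision and particles
re-enter the fluid with 10⁻¹² m clearance. Particles sitting on the floor
with a net downward force are treated as at rest (the micro-bounce cycle
has zero net displacement and the no-slip fluid velocity vanishes there);
they wake as soon as a lifting force applies. A particle crossing the
outlet plane becomes "recirculating" and re-enters at the inlet after the
loop transit delay, at a height resampled uniformly over the inlet opening
from its own RNG substream. Seeding is uniform over the fluid section with
initial velocity equal to the local fluid velocity; per-particle
`SeedSequence` substreams make the first k particles independent of
ensemble size.

Not modeled: Brownian motion (Péclet ≫ 1 at these sizes and speeds), lift
forces, particle–particle interaction, adhesion, deformation, and finite
particle radius in wall contact (point-particle convention).

## Membrane-crossing rule and calibration

Crossing at a membrane contact requires all three of: protrusion force
switched on, net membrane-normal force positive (F_prot exceeds the
buoyant weight), and a Bernoulli success with the configured crossing
probability (default 1). Consequences the tests verify:

* with F_prot = 0 the extravasated count is exactly zero for any seed and
  duration — the flow-only null;
* the extravasated fraction is non-decreasing in F_prot (5-point ladder,
  fixed seed) and in duration.

Calibration inverts the fraction–force map by bisection using common
random numbers (every evaluation re-traces the same seeded ensemble, so
the map is a deterministic step function and bisection is valid). The
returned force is the smallest magnitude in the bracket (default
[0, 10⁻¹⁰] N) whose fraction lies within the tolerance of the target; the
tolerance must exceed twice the binomial standard error of the target at
the chosen ensemble size, otherwise the call refuses. The ~2 % observed
fraction is an experimental anchor; the calibrated force is model-implied
under the stated conditions (ensemble size, tracing window), not a
measurement. With n = 500 and a 300 s window the map's particle-flip
spacing near 4×10⁻¹² N is below 2×10⁻¹³ N, which bounds the recovery
error of a planted ground-truth force.

## Synthetic benchmarks

`make_benchmark_suite` writes five configs whose expected values are
computed from closed forms at generation time and stored with the formula
string: Poiseuille tube (u_max = 1.273 cm/s), quiescent settling box
(v_s = 6.28 µm/s, floor-crossing time h/v_s = 239 s), uniform-advection
duct (drag fixed point), reference device flow-only (fraction 0), and
reference device with F_prot = 10⁻¹¹ N (fraction > 0). These are the same
oracles the test suite and `oocflow validate` run. What passing them shows
is agreement with the idealized physics (laminar closed forms, Stokes
regime); it does not validate biological fidelity — cell deformability,
adhesion and the real membrane pore mechanics are outside the model.

## Problem sizes and determinism

Default resolutions are chosen for a single-CPU desk run: 50 µm grids
(≈11 000 fluid cells, subsecond solve), ensembles of 200–1000 particles,
tracing windows from 300 s (calibration) to 4 h (flow-only null). Every
stochastic stage takes an explicit seed; `run_pipeline` re-runs
bit-identically and records the seed, residuals and library versions in
its log. Output floats carry 17 significant digits so every file format
round-trips exactly.
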