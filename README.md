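# oocflow

Desk-scale simulation of circulating immune cells in a perfused
tumor-on-chip device. A transwell insert holding a 3-D tumor culture sits
above a fluid chamber through which Natural Killer (NK) cells are pumped at
a capillary-like rate; the cells may leave the circulation by crossing the
porous membrane upward into the tumor compartment ("extravasation"). The
package answers two questions quantitatively:

1. What does the perfusion flow look like, and can it passively push cells
   across the membrane? (No — flow alone produces exactly zero crossings.)
2. How large a chemotactic **protrusion force** per cell is needed to
   reproduce the extravasated fraction observed experimentally (~2 % of
   circulating cells)?

It is written for microphysiological-systems and biofluid-mechanics
researchers who want a transparent, testable alternative to black-box CFD
for this class of device.

## Model

**Flow.** Steady incompressible laminar Navier–Stokes,

```
ρ (u_f·∇)u_f = −∇p + μ ∇²u_f,     ∇·u_f = 0,
```

with ρ = 1000 kg/m³, μ = 10⁻³ Pa·s (water-like medium), a parabolic inlet
profile carrying Q = 0.3 ml/min, p = 0 at the outlet, and no-slip walls
(the membrane is impermeable to the fluid). Discretized on a staggered MAC
grid — axisymmetric (x, r) for tube benchmarks, 2-D longitudinal section
(x, z) for the device — and solved as a sparse saddle-point system. At the
device's channel Reynolds number (≈6.4) the creeping-flow form is the
default; the convective term can be enabled (Picard iteration) and shifts
the peak speed by <1 %.

**Cells.** NK cells are rigid spheres (r_p = 6 µm, ρ_p = 1080 kg/m³),
one-way coupled to the frozen flow field:

```
d(m_p v_p)/dt = F_d + F_g,   F_d = 6πμ r_p (u_f − v_p),
F_g = m_p g (ρ_p − ρ)/ρ_p   (downward).
```

The drag relaxation time τ = m_p/(6πμ r_p) ≈ 8.6 µs makes the ODE stiff;
the integrator uses its exact exponential solution per step (or the
overdamped limit v_p = u_f + drift). Walls rebound cells specularly with
speed preserved exactly. Cells leaving the outlet re-enter at the inlet
after a plug-flow delay through the unmeshed 1.5 ml circuit.

**Extravasation.** A membrane contact leads to crossing only if a
protrusion force F_prot (constant magnitude, membrane-normal, active only
beneath the membrane footprint) is switched on, the net normal force is
upward (F_prot > 7.1×10⁻¹³ N buoyant weight), and a Bernoulli draw with
the crossing probability succeeds. The extravasated fraction is monotone
in F_prot, so a bisection with common random numbers calibrates F_prot
against an observed fraction.

## Worked example

```python
from oocflow import (FluidProperties, ParticleProperties, ForceConfig,
                     build_reference_device, rasterize, solve_steady_flow,
                     flow_metrics, trace_ensemble)

Q = 0.3e-6 / 60                       # 0.3 ml/min in m³/s
geom  = build_reference_device()      # Ø1 mm channels, 16×1.5 mm chamber
grid  = rasterize(geom, 50e-6)
field = solve_steady_flow(grid, FluidProperties(), Q)
m = flow_metrics(field, grid, FluidProperties())
print(f"max speed {m.max_speed*100:.3f} cm/s, Re {m.reynolds:.2f}")

res = trace_ensemble(geom, field, ParticleProperties(),
                     ForceConfig(overdamped=True), n=500,
                     duration=3600.0, dt=0.02, seed=2024)
print(f"extravasated {res.n_extravasated}/{res.n}")
```

prints

```
max speed 1.269 cm/s, Re 6.37
extravasated 0/500
```

The peak speed sits at the top of the physiological capillary blood-flow
range (~0–1.2 cm/s), and with no protrusion force not a
single cell crosses the membrane in an hour of device time — passive
transport cannot produce extravasation. The analysis drivers
(`analysis/01_solve_flow.py` … `03_calibrate_protrusion.py`) run the full
story: flow metrics, flow-only vs protrusion scenario contrast, and the
calibration of the protrusion force against the observed ~2 % fraction.

A CLI mirrors the pipeline: `oocflow simulate-flow / trace-cells / analyze
/ calibrate / validate / make-fixtures / run` (configs in mm, ml/min and
hours; see `oocflow make-fixtures --out fixtures/` for examples).

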