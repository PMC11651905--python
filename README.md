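# striderslide

Floatability and resistance of water striders (Gerridae) passively
sliding on the water surface.

After the propulsive stroke of its midlegs, a water strider coasts
across the surface during the recovery phase, supported only by
surface tension acting along the wetted perimeter of its legs.  Whether
it can do this at all — and how quickly it decelerates — depends on
body mass, wetted-leg geometry and gait.  In the **symmetric** gait the
body rides on two short forelegs and two hindlegs; in the
**asymmetric** gait one midleg is extended forward as the anterior
support.  Large-bodied species face a floatability problem: the
anterior support force can exceed the maximum force surface tension
can supply under short forelegs, piercing the meniscus.

This package is for biomechanists and biophysicists who want a
quantitative, testable model of that regime: it predicts which
combinations of body-size class, wetted-leg geometry (short /
intermediate / long wetted forelegs) and gait can slide without
breaking the surface, and how the two gaits compare in sliding
deceleration.

## Model

At sliding speed `U` the quasi-static balance for the anterior and
posterior normal forces `Na`, `Np` is

```
Na + Np = m g
Na a − Np b = h (Ra + Rp)          ⇒   Na = (m g b + h (Ra + Rp)) / (a + b)
```

with `a`, `b` the horizontal distances from the centre of mass to the
anterior/posterior contacts and `h` the height of the COM above the
surface: sliding resistance pitches the body tail-up and presses the
forelegs down.  The resistance on each leg set has two parts:

* hydrodynamic drag `Fh = ½ C_D ρ U² A` — Blasius skin friction
  (`C_D = 1.328 Re_L^−½`, `A = (π D/2) L`) for a leg parallel to the
  motion, cylinder crossflow (`C_D = 1 + 10 Re_D^−⅔`, `A = D L`) for an
  orthogonal leg;
* capillary-gravity wave drag, zero below the minimum phase speed
  `c = (4 g σ / ρ)^¼ = 0.2313 m s⁻¹` and
  `Fw = N² / (4 π² σ L²) · ℓ_c · W0 · w(U/c)` above it, where
  `ℓ_c = √(σ/ρg)` is the capillary length and `w` a pluggable onset
  kernel (default: peaked just above `c`).

Because `Fw` depends on the load `N`, the balance is solved by damped
fixed-point iteration (cross-checked against bisection in the tests).
The anterior support fails — the meniscus breaks — when
`Na > 2 σ (La + D)`, the maximum surface-tension force along the
anterior wetted perimeter.  Passive slides integrate
`m dU/dt = −(Ra + Rp)` with fixed-step RK4, re-solving the statics at
every stage.

A synthetic-morphology module provides calibrated defaults for five
body-size classes (12–511 mg) and three wetted-leg-geometry classes
(forelegs carrying roughly 1–3%, 4–8% or 12–14% of the total wetted
length), plus stride-event generators for gait-plasticity summaries.

## Worked example

```python
import striderslide as ss

fluid = ss.FluidProperties()          # water: rho=1000, nu=1e-6, sigma=0.073, g=9.81
model = ss.WaveDragModel()            # default peaked kernel, calibrated amplitude

# a medium-sized slider (A. paludum class) in the symmetric gait
cfg = ss.default_configuration("intermediate", "A_paludum", "symmetric")
sol = ss.check_floatability(cfg, 0.5, fluid, model)
print(sol.Na, sol.critical_force, sol.breaks)
# 3.406e-04 N on the forelegs vs a 5.694e-04 N capillary maximum -> floats

print(ss.deceleration_at(cfg, 0.5, fluid, model))
# 3.288 m/s^2 of wave-dominated deceleration at 0.5 m/s

traj = ss.simulate_slide(cfg, 0.6, fluid, model)
print(traj.termination, traj.distance, traj.duration)
# 'time_limit' 0.3153 m in 2.0 s (the slide outlasts the 2 s window)

# the heaviest class cannot rest on its short forelegs even at U = 0
giant = ss.default_configuration("short", "G_gigas_male", "symmetric")
print(ss.check_floatability(giant, 0.0, fluid, model).breaks)
# True: Na = 2.028e-03 N exceeds the 8.760e-04 N capillary maximum
```

The same computations are available from the shell:

```
striderslide floatability --u 0.5
striderslide slide --u0 0.6 --out out/
striderslide phase-table --seed 7 --out out/
striderslide events --n 236 --seed 7 --out out/
striderslide selfcheck
```

`phase-table` sweeps all 3 geometries x 5 size classes x 2 gaits x 3
anterior-support scenarios on a 12 x 25 (mass, velocity) grid each and
writes the per-point phase diagram (`phase_points.csv`) and the
classification summary (`floatability_table.csv`,
`floatability_summary.json`): asymmetric sliding floats in every
condition, long-foreleg symmetric sliding floats at every size, and
intermediate-foreleg symmetric sliding fails for the three largest
classes.

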