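# Methods

## Scope and assumptions

The package models the *recovery phase* of water-strider locomotion:
the passive slide (or the launch conditions of a leap) after the
propulsive stroke.  Propulsion hydrodynamics, braking, post-stroke
body-pitch rotation and leg-hair microstructure are outside scope.
The body is a rigid mass on two supporting leg sets; each wetted leg is
a smooth cylinder of length `L` and diameter `D` resting in (not
through) the interface.  The pitch degree of freedom is assumed
instantaneously balanced (quasi-static statics at every speed), which
is consistent with the slow, monotonic decelerations the model
produces.

Units are SI throughout the library; mg and mm appear only at the I/O
boundary.

## Support balance

With the COM at height `h` above the surface, anterior contact a
distance `a` ahead of the COM and posterior contact `b` behind it,
force and torque balance give

    Na + Np = m g,
    Na = (m g b + h (Ra + Rp)) / (a + b).

Resistance enters only through the pitching torque `h (Ra + Rp)`,
which always *adds* anterior load.  Because the wave drag depends on
the normal forces, `Na` is a fixed point of a one-dimensional map; it
is found by (optionally damped) fixed-point iteration from the
zero-resistance lever rule, converged at `|ΔNa| < max(1e-12 N,
1e-10·Na)` within 200 iterations.  The map has the local form
`Na ← A + B·Na²`; when `4AB > 1` it has no fixed point (wave-drag
feedback runaway).  Such points are reported as `infeasible` with
`breaks=True` — an unbounded anterior load certainly pierces the
surface — and never raised, so parameter sweeps always complete.
The tests cross-check the fixed point against an independent bisection
(Brent) root finder to 1e-9 N on 100 seeded configurations.

Floatability uses the capillary maximum of the anterior set,
`Na,crit = 2 σ Σ(L_i + D_i)`; the wetted perimeters of a multi-leg set
add, matching the summed-perimeter axis of the phase diagrams.

## Resistance closures

**Hydrodynamic drag** is summed per leg, `Fh = ½ C_D ρ U² A`:

* parallel leg (the normal posture): half the cylinder surface is
  wetted, `A = (π D / 2) L`, and `C_D = 1.328 Re_L^{-1/2}` with
  `Re_L = U L / ν` — the laminar flat-plate (Blasius) coefficient at
  the per-leg length Reynolds number (Re_L ~ 10³–10⁵ here, below the
  classical transition);
* orthogonal leg (the atypical extreme foreleg posture):
  `A = D L`, `C_D = 1 + 10 Re_D^{-2/3}` with `Re_D = U D / ν`, a
  standard circular-cylinder crossflow fit for Re_D ~ 10–10³.

Both closures are pluggable.  Note the per-leg Reynolds number means
drag is additive over identical legs but *not* invariant under
splitting one leg into two shorter ones (splitting a parallel leg in
half raises its skin friction by √2 — the leading-edge effect).

**Capillary-gravity wave drag** is shed only above the minimum phase
speed `c = (4 g σ / ρ)^{1/4}` (0.2313 m/s for the default water
properties).  The implemented closure is

    Fw = N² / (4 π² σ L²) · ℓ_c · W0 · w(U/c),

quadratic in the supported load `N` in the spirit of the classic
point-force wave-resistance result `Fw ~ N² k / σ`, attenuated by
`(ℓ_c / L)²` for contacts long compared with the capillary length
`ℓ_c = √(σ / ρ g)` (2.73 mm).  `W0` (dimensionless amplitude) and the
onset kernel `w(x)` are the acknowledged uncertainty of the model and
are pluggable:

* `peaked` (default): `w(x) = √(1 − x⁻⁴) / √x`, zero at the onset,
  maximal at `x = 5^{1/4}` (≈ 0.35 m/s on water), decaying like
  `x^{-1/2}` — a fast slider outruns its wave train;
* `saturating`: `w(x) = √(1 − x⁻⁴)`, monotone to 1.  With a monotone
  kernel the anterior load `Na(U)` is provably non-decreasing in
  speed, and the monotonicity property tests use it; the peaked
  default trades that guarantee for the empirically supported decay of
  wave resistance at high speed, which is what localises the
  gait-comparison deceleration gap at moderate speeds and lets fast,
  large-bodied sliders break the surface where slow ones do not.

## Sliding dynamics

`m dU/dt = −(Ra(U) + Rp(U))`, integrated with fixed-step classical
RK4 (default `dt = 1e-4 s`), statics re-solved at every stage with a
warm start from the previous evaluation.  Fixed-step integration keeps
trajectories bit-reproducible for a given configuration; the tests
compare RK4 at `dt = 1e-4` against explicit Euler at `dt = 1e-6` and
require 0.1% agreement on sliding distance.  A slide terminates at
`U ≤ 0.01 m/s` (treated as rest — far below any wave effect), at
`t = 2 s`, or at the first step whose statics solution breaks the
meniscus; post-break motion is recorded as a termination cause, not
modelled.

## Synthetic morphologies (the study conditions)

Five body-size classes with their observed mass and sliding-speed
ranges:

| class            | mass (mg) | U (m/s) | body length | wetted ΣL | D (mm) | h (mm) |
|------------------|-----------|---------|-------------|-----------|--------|--------|
| G_latiabdominis  | 12–32     | 0–1.0   | 12.3 mm     | 40 mm     | 0.15   | 3      |
| A_paludum        | 35–72     | 0–1.5   | 15.0 mm     | 70 mm     | 0.20   | 4      |
| P_tigrina        | 83–144    | 0–2.5   | 17.0 mm     | 110 mm    | 0.25   | 5      |
| G_gigas_female   | 217–318   | 0–2.5   | 32.6 mm     | 220 mm    | 0.35   | 6      |
| G_gigas_male     | 316–511   | 0–2.5   | 36.0 mm     | 260 mm    | 0.40   | 6      |

Lever arms: `a = 0.30·BL` for foreleg support, `0.45·BL` for the
forward-extended midleg; `b = 0.30·BL`.  Within a class the total
wetted length scales as `(m / m_mid)^{1/3}` (mild within-class
allometry; the cross-class table carries the real allometry).  These
wetted lengths, diameters and lever arms are *calibrated defaults*,
not measured specimen values: they follow the documented class masses
and the known allometric trend, and together with `W0 = 25` they were
fixed once — by design arithmetic, before any test was run — so that
the default model reproduces the qualitative floatability pattern of
the study system (see below).  Real per-specimen morphologies can be
supplied via the morphology CSV or JSON configuration instead.

Three wetted-leg-geometry classes, with the share of the total wetted
length on (fore, mid, hind) legs:

* short: (0.02, 0.40, 0.58), sampled foreleg share 1–3%;
* intermediate ("standard"): (0.05, 0.40, 0.55), sampled 4–8%;
* long: (0.13, 0.42, 0.45), sampled 12–14%.

The representative intermediate foreleg share of 0.05 sits inside the
observed 4–8% cluster; together with the midleg share of 0.40 it makes
the asymmetric *minimal* midleg support (half the tibiotarsal segment,
`L = 0.10·ΣL`) carry exactly the same Blasius skin friction as the two
forelegs (`2·√(fΣL/2) = √(0.10·ΣL)` under the √L scaling).  That
calibration isolates the wave-drag channel as the entire
gait-comparison signal below and above the threshold.  Its cost is a
hindleg wetted share slightly exceeding the midleg share, which
overstates hindleg length for the intermediate class.

Anterior-support scenarios mirror the observed postural variation:
`parallel_full` (foreleg tarsi / midleg tarsus+tibia, parallel),
`parallel_minimal_midleg` (asymmetric support wets only half the
tibiotarsal segment — the minimum seen in medium-sized sliders), and
`orthogonal` (symmetric forelegs across the flow; the supporting
midleg is always held parallel, as observed, so asymmetric
configurations are unchanged in this scenario).

**Stride events** draw a gait (symmetric slide / asymmetric slide /
leap at proportions 100:86:50) and a lognormal launch speed per gait
(medians 0.25, 0.40, 0.65 m/s; log-SDs 0.70, 0.65, 0.30).  The
asymmetric parameters put the lower quartile near 0.26 m/s and ~75–80%
of launches above `c`, emulating the observed preference for the
asymmetric gait exactly where symmetric sliding pays wave drag.
Distances and durations come from simulating each slide on the default
medium-class morphology (leaps use the symmetric configuration — their
recorded "distance" is therefore a sliding-equivalent, not a ballistic
range).  Quartiles use linear interpolation between order statistics
(numpy's default, the common "type 7" rule).

What the generator does *not* emulate: real per-specimen covariance
between mass and leg geometry, within-individual postural variation,
flowing-water corrections, and the animal's decision to end a slide by
touching down its midlegs.  Passing tests therefore show internal
consistency of the model under the documented study conditions, not
agreement with any particular specimen's measurements.

## Phase-diagram pipeline

Each situation (geometry x size x gait x scenario) is swept on a
12 x 25 (mass, velocity) grid spanning the class ranges, at the
representative geometry split (per-point sampling over the printed
geometry ranges is available, seeded).  Each point records the
anterior wetted perimeter `2Σ(L+D)`, the converged `Na` and the break
flag; situations classify by exact set operations — `always_floats`
(no point breaks), `always_breaks` (every point, including `U = 0`),
`breaks_when_fast` (anything between).  With the default calibration:
asymmetric sliding floats in all 45 conditions; long-foreleg symmetric
sliding floats at every size; intermediate-foreleg symmetric sliding
floats for the two smallest classes and fails for the three largest;
short-foreleg symmetric sliding fails almost everywhere and for the
giant class already at rest; the orthogonal foreleg posture induces
breaking at speed even for the small intermediate classes.

## Numerical choices and degenerate inputs

* Fixed-point tolerance 1e-12 N absolute / 1e-10 relative, 200
  iterations; runaway declared beyond 50x body weight.
* Wave drag of a loaded, super-critical contact of zero wetted length
  raises a singular-configuration error; zero-length legs contribute
  no hydrodynamic drag.
* `U = 0` short-circuits to the exact lever rule; a slide launched at
  or below `U_stop` terminates immediately with zero distance.
* Ties at the classification boundaries are exact flag operations — no
  fractional cutoffs.
* CSV output uses fixed column order, '.' decimal, ',' separator and
  LF endings; repeated runs are byte-identical.

## Problem sizes

The default sweep is 90 situations x 300 grid points (27 000 statics
solves, a few seconds).  The integrator cross-check runs 0.4 s of
simulated sliding at `dt = 1e-6` (4x10⁵ Euler steps, ~10 s); stride-event
sets default to 236 events, matching the size of the observed event
set.

## Known limitations

* The wave-drag amplitude and kernel are calibrated stand-ins for an
  unavailable wetted-area shape function; absolute wave-drag magnitudes
  should not be read quantitatively, only the threshold structure and
  the relative gait/geometry comparisons.
* The laminar skin-friction closure is untested for the hairy,
  waterline-piercing legs of the largest species at Re ~ 10⁵.
* Quasi-static pitch balance ignores the transient anterior loading
  from post-stroke body rotation, so floatability predictions are
  slightly optimistic near the boundary.
* The heavier-decelerates-less trend holds in the skin-friction regime;
  the load-quadratic wave drag reverses it for fast symmetric sliding
  on short forelegs.
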