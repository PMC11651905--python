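"""Coupled support-force balance and the meniscus-breaking criterion.

At a given sliding speed U the insect is in quasi-static equilibrium:

* gravity balance:      Na + Np = m g
* pitch-torque balance: Na a - Np b = h (Ra + Rp)

with torques taken about the centre of mass (x forward, z up, anterior
contact at +a, posterior at -b, resistance acting at depth h below the
COM).  Eliminating Np gives

    Na = (m g b + h (Ra + Rp)) / (a + b),

so sliding resistance always *adds* anterior load: the tail-up pitching
torque presses the front legs down.  Because the wave drag inside
Ra + Rp itself depends on Na and Np, the balance is solved by damped
fixed-point iteration started from the zero-resistance lever rule.

The anterior support fails — the meniscus breaks and the leg pierces
the surface — when Na exceeds the maximum force surface tension can
supply along the anterior wetted perimeter, ``2 sigma (La + D)`` summed
over the anterior legs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import DomainError, FluidProperties, SliderConfiguration, SupportLegSet
from .resistance import ResistanceBreakdown, WaveDragModel, total_resistance

__all__ = [
    "StaticsSolution",
    "solve_support_forces",
    "critical_support_force",
    "check_floatability",
]

ABS_TOL = 1e-12  # N
REL_TOL = 1e-10
MAX_ITER = 200
# Iterates beyond this multiple of body weight are treated as runaway:
# the Na <- quadratic-in-Na map has no fixed point and the anterior
# load grows without bound (the insect certainly breaks the surface).
RUNAWAY_FACTOR = 50.0


@dataclass(frozen=True)
class StaticsSolution:
    """Converged (or flagged) support forces at one sliding speed."""

    Na: float
    Np: float
    Ra: float
    Rp: float
    U: float
    converged: bool
    iterations: int
    critical_force: float
    infeasible: bool = False

    @property
    def margin(self) -> float:
        """critical_force - Na (N); negative means the meniscus breaks."""
        return self.critical_force - self.Na

    @property
    def breaks(self) -> bool:
        return self.margin < 0.0

    @property
    def total_resistance(self) -> float:
        return self.Ra + self.Rp


def critical_support_force(legs: SupportLegSet, sigma: float) -> float:
    """Maximum surface-tension force 2 sigma sum(L_i + D_i) a leg set can carry (N).

    For a multi-leg set the wetted perimeters add, matching the summed
    anterior wetted perimeter used on the phase-diagram axis.
    """
    if not (math.isfinite(sigma) and sigma > 0):
        raise DomainError(f"sigma must be > 0, got {sigma!r}")
    return 2.0 * sigma * legs.total_perimeter_term


def solve_support_forces(
    config: SliderConfiguration,
    U: float,
    fluid: FluidProperties,
    model: WaveDragModel,
    *,
    damping: float = 1.0,
    warm_start: float | None = None,
) -> StaticsSolution:
    """Solve the gravity/torque balance for Na, Np at speed U.

    Returns a :class:`StaticsSolution`; non-convergence and infeasible
    (Np < 0) outcomes are reported through flags, never raised, so that
    phase sweeps can record them.

    Parameters
    ----------
    damping:
        Relaxation factor applied to each fixed-point update (1 = undamped).
    warm_start:
        Optional initial Na guess (e.g. the solution at a neighbouring
        speed); defaults to the zero-resistance lever rule.
    """
    if U < 0:
        raise DomainError(f"speed must be >= 0, got {U!r}")
    mg = config.mass * fluid.g
    a, b, h = config.a, config.b, config.h
    crit = critical_support_force(config.anterior, fluid.sigma)
    lever_na = mg * b / (a + b)

    na = lever_na if warm_start is None else min(max(warm_start, 0.0), RUNAWAY_FACTOR * mg)
    converged = False
    iterations = 0
    runaway = False
    for iterations in range(1, MAX_ITER + 1):
        np_ = mg - na
        ant, post = total_resistance(U, max(na, 0.0), max(np_, 0.0), config, fluid, model)
        na_target = (mg * b + h * (ant.total + post.total)) / (a + b)
        na_next = na + damping * (na_target - na)
        step = abs(na_next - na)
        na = na_next
        if na > RUNAWAY_FACTOR * mg:
            runaway = True
            break
        if step < max(ABS_TOL, REL_TOL * abs(na)):
            converged = True
            break

    np_ = mg - na
    ant, post = total_resistance(U, max(na, 0.0), max(np_, 0.0), config, fluid, model)
    infeasible = runaway or np_ < 0.0
    return StaticsSolution(
        Na=na,
        Np=np_,
        Ra=ant.total,
        Rp=post.total,
        U=U,
        converged=converged and not infeasible,
        iterations=iterations,
        critical_force=crit,
        infeasible=infeasible,
    )


def check_floatability(
    config: SliderConfiguration,
    U: float,
    fluid: FluidProperties,
    model: WaveDragModel,
) -> StaticsSolution:
    """Solve the statics at speed U and report the floatability margin.

    The returned solution's ``breaks`` flag is True when the anterior
    normal force exceeds the critical surface-tension force
    2 sigma (La + D) of the anterior leg set.
    """
    return solve_support_forces(config, U, fluid, model)
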