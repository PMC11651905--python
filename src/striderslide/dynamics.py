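"""Passive-sliding trajectories.

During the recovery phase the insect coasts: the equation of motion is

    m dU/dt = -(Ra(U) + Rp(U)),

with the quasi-static support balance re-solved at every integrator
stage (the pitch degree of freedom is assumed instantaneously
balanced).  Integration is classical fixed-step 4th-order Runge-Kutta;
a fixed step keeps trajectories bit-reproducible across platforms for a
given configuration.  A slide terminates when the speed drops below a
rest threshold, when a time limit is reached, or at the first step
whose statics solution breaks the meniscus (post-break motion is
recorded as a termination cause, not modelled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .core import DomainError, FluidProperties, SliderConfiguration
from .resistance import WaveDragModel
from .statics import StaticsSolution, solve_support_forces

__all__ = [
    "Trajectory",
    "StopCriteria",
    "deceleration_at",
    "simulate_slide",
    "gait_deceleration_gap",
]


@dataclass(frozen=True)
class StopCriteria:
    """Termination thresholds for a simulated slide.

    ``U_stop`` treats slower motion as rest (default 0.01 m/s, far below
    any measurable wave effect); ``t_max`` caps the integration.
    """

    U_stop: float = 0.01
    t_max: float = 2.0


@dataclass
class Trajectory:
    """Time series of one passive slide."""

    times: list[float]
    velocities: list[float]
    positions: list[float]
    decelerations: list[float]
    statics_per_step: list[StaticsSolution | None]
    termination: str  # "stopped" | "time_limit" | "meniscus_break"

    @property
    def distance(self) -> float:
        return self.positions[-1] - self.positions[0]

    @property
    def duration(self) -> float:
        return self.times[-1] - self.times[0]


def deceleration_at(
    config: SliderConfiguration,
    U: float,
    fluid: FluidProperties,
    model: WaveDragModel,
    *,
    warm_start: float | None = None,
) -> float:
    """Instantaneous deceleration (Ra + Rp) / m at speed U, in m/s^2."""
    sol = solve_support_forces(config, U, fluid, model, warm_start=warm_start)
    return sol.total_resistance / config.mass


def simulate_slide(
    config: SliderConfiguration,
    U0: float,
    fluid: FluidProperties,
    model: WaveDragModel,
    *,
    dt: float = 1e-4,
    stop: StopCriteria | None = None,
    include_resistance: bool = True,
    method: str = "rk4",
) -> Trajectory:
    """Integrate a passive slide from initial speed U0.

    Parameters
    ----------
    dt:
        Fixed integrator step in seconds.
    stop:
        Termination thresholds; defaults to :class:`StopCriteria`.
    include_resistance:
        With False the slide is force-free (useful as an exact
        free-coasting reference); no statics are solved and the velocity
        is preserved bit-exactly.
    method:
        ``"rk4"`` (default) or ``"euler"`` (the internal fine-step
        cross-check).

    Notes
    -----
    The statics solver is warm-started from the previous evaluation, so
    the per-stage re-solve typically converges in a couple of
    iterations.  The recorded deceleration at each step satisfies
    ``dec_k * m = (Ra + Rp)_k`` for the step-start statics solution.
    """
    if U0 < 0:
        raise DomainError(f"initial speed must be >= 0, got {U0!r}")
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt!r}")
    if method not in ("rk4", "euler"):
        raise DomainError(f"unknown integration method {method!r}")
    stop = stop or StopCriteria()

    times = [0.0]
    velocities = [U0]
    positions = [0.0]
    decelerations: list[float] = []
    statics: list[StaticsSolution | None] = []

    # warm-start memory shared across statics evaluations
    last_na: list[float | None] = [None]

    def accel(u: float) -> tuple[float, StaticsSolution | None]:
        if not include_resistance or u <= 0.0:
            return 0.0, None
        sol = solve_support_forces(config, u, fluid, model, warm_start=last_na[0])
        if sol.converged or sol.infeasible:
            last_na[0] = sol.Na
        return -sol.total_resistance / config.mass, sol

    t, u, x = 0.0, U0, 0.0
    termination = "time_limit"

    if u <= stop.U_stop:
        a0, sol0 = accel(u)
        decelerations.append(-a0)
        statics.append(sol0)
        return Trajectory(times, velocities, positions, decelerations, statics, "stopped")

    while True:
        a1, sol1 = accel(u)
        decelerations.append(-a1)
        statics.append(sol1)
        if sol1 is not None and sol1.breaks:
            termination = "meniscus_break"
            break
        if t >= stop.t_max:
            termination = "time_limit"
            break
        if sol1 is not None and sol1.infeasible and not sol1.breaks:
            raise DomainError(
                f"statics diverged mid-run at U={u:.4g} m/s without breaking; cannot continue"
            )

        if method == "euler":
            u_new = u + dt * a1
            x_new = x + dt * u
        else:
            k1 = a1
            u2 = max(u + 0.5 * dt * k1, 0.0)
            k2, _ = accel(u2)
            u3 = max(u + 0.5 * dt * k2, 0.0)
            k3, _ = accel(u3)
            u4 = max(u + dt * k3, 0.0)
            k4, _ = accel(u4)
            u_new = u + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            # position advanced with the matching velocity quadrature
            x_new = x + dt / 6.0 * (u + 2.0 * u2 + 2.0 * u3 + u4)

        u_new = max(u_new, 0.0)
        t += dt
        u, x = u_new, x_new
        times.append(t)
        velocities.append(u)
        positions.append(x)

        if u <= stop.U_stop:
            a_end, sol_end = accel(u)
            decelerations.append(-a_end)
            statics.append(sol_end)
            termination = "stopped"
            break

    # pad the per-step lists to the sample count when we broke out before
    # appending (meniscus break / time limit record the triggering sample)
    while len(decelerations) < len(times):
        decelerations.append(decelerations[-1])
        statics.append(statics[-1])

    return Trajectory(times, velocities, positions, decelerations, statics, termination)


def gait_deceleration_gap(
    sym_config: SliderConfiguration,
    asym_config: SliderConfiguration,
    U_grid: Sequence[float],
    fluid: FluidProperties,
    model: WaveDragModel,
) -> list[tuple[float, float]]:
    """Signed deceleration gap dec(symmetric) - dec(asymmetric) per grid speed.

    Both configurations must share the same body mass (same insect, two
    gaits).  Below the critical wave speed the gap reduces to the
    skin-friction difference between the anterior supports; above it the
    wave drag on the short forelegs dominates and the gap opens up.
    """
    if not math.isclose(sym_config.mass, asym_config.mass, rel_tol=1e-9):
        raise DomainError(
            f"gait comparison requires equal masses, got {sym_config.mass} and {asym_config.mass}"
        )
    out = []
    for U in U_grid:
        dec_s = deceleration_at(sym_config, U, fluid, model)
        dec_a = deceleration_at(asym_config, U, fluid, model)
        out.append((U, dec_s - dec_a))
    return out
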