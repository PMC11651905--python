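"""Resistance forces on a sliding leg set.

Two mechanisms slow a passively sliding water strider:

* **hydrodynamic drag** ``Fh = 1/2 * C_D * rho * U^2 * A`` on the wetted
  area of each leg.  For a leg parallel to the motion the drag is shear
  dominated and we close ``C_D`` with the laminar flat-plate (Blasius)
  law ``1.328 * Re_L**-0.5``; for an orthogonal leg it is pressure
  dominated and we use the classical circular-cylinder crossflow fit
  ``1 + 10 * Re_D**(-2/3)``.

* **capillary-gravity wave drag** ``Fw``, shed only above the minimum
  phase speed ``c = (4 g sigma / rho)**0.25`` of capillary-gravity
  waves (0.2313 m/s on water).  The load dependence is quadratic in the
  supporting normal force N and inversely quadratic in the wetted
  length, in the spirit of the classic point-force wave-resistance
  result ``Fw ~ N^2 k / sigma``; we write

      Fw = N**2 / (4 * pi**2 * sigma * L**2) * l_c * W0 * w(U / c)

  where ``l_c = sqrt(sigma / rho / g)`` is the capillary length (which
  closes the dimensions), ``W0`` a dimensionless calibration amplitude
  and ``w`` a dimensionless onset kernel in ``x = U / c``.  Both the
  amplitude and the kernel are pluggable so a refined wetted-area shape
  function can be dropped in without touching anything else.

Two kernels ship with the package:

* :func:`saturating_kernel` — ``sqrt(1 - x**-4)``, zero at the onset and
  rising monotonically to 1; the simplest switch-on.
* :func:`peaked_kernel` (default) — ``sqrt(1 - x**-4) / sqrt(x)``, which
  peaks shortly above the onset (at ``x = 5**0.25``, about 0.35 m/s on
  water) and then decays, reflecting that wave resistance of a small
  moving disturbance is strongest just above the critical speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .core import (
    DomainError,
    FluidProperties,
    Orientation,
    Role,
    SliderConfiguration,
    SupportLegSet,
    capillary_length,
)

__all__ = [
    "WaveDragModel",
    "ResistanceBreakdown",
    "SingularConfigurationError",
    "critical_wave_speed",
    "hydrodynamic_drag",
    "wave_drag",
    "total_resistance",
    "saturating_kernel",
    "peaked_kernel",
    "KERNELS",
    "DEFAULT_WAVE_AMPLITUDE",
]


class SingularConfigurationError(DomainError):
    """A loaded, moving contact of zero wetted length has no finite wave drag."""


def saturating_kernel(x: float) -> float:
    """Onset kernel sqrt(1 - x**-4): 0 at x<=1, monotone, -> 1 as x -> inf."""
    if x <= 1.0:
        return 0.0
    return math.sqrt(1.0 - x ** -4)


def peaked_kernel(x: float) -> float:
    """Onset kernel sqrt(1 - x**-4) / sqrt(x).

    Zero at the onset, maximal at x = 5**(1/4) ~ 1.50 and decaying like
    x**-1/2 beyond: fast sliders outrun their own wave train.
    """
    if x <= 1.0:
        return 0.0
    return math.sqrt(1.0 - x ** -4) / math.sqrt(x)


KERNELS: dict[str, Callable[[float], float]] = {
    "peaked": peaked_kernel,
    "saturating": saturating_kernel,
}

# Dimensionless wave-drag amplitude, calibrated once so that the default
# synthetic morphologies reproduce the observed floatability pattern
# across size classes and gaits (see docs/methods.md).
DEFAULT_WAVE_AMPLITUDE = 25.0


@dataclass(frozen=True)
class WaveDragModel:
    """Pluggable wave-drag closure: onset kernel w(x) plus amplitude W0."""

    kernel: Callable[[float], float] = peaked_kernel
    amplitude: float = DEFAULT_WAVE_AMPLITUDE

    def __post_init__(self) -> None:
        if not (math.isfinite(self.amplitude) and self.amplitude >= 0):
            raise DomainError(f"wave-drag amplitude must be >= 0, got {self.amplitude!r}")

    @classmethod
    def from_name(cls, kernel: str = "peaked", amplitude: float = DEFAULT_WAVE_AMPLITUDE) -> "WaveDragModel":
        try:
            fn = KERNELS[kernel]
        except KeyError:
            raise DomainError(f"unknown wave-drag kernel {kernel!r}; known: {sorted(KERNELS)}") from None
        return cls(kernel=fn, amplitude=amplitude)


@dataclass(frozen=True)
class ResistanceBreakdown:
    """Hydrodynamic and wave components of the resistance on one leg set."""

    F_h: float
    F_w: float
    applied_to: Role

    def __post_init__(self) -> None:
        if self.F_h < 0 or self.F_w < 0:
            raise DomainError("resistance components must be >= 0")

    @property
    def total(self) -> float:
        return self.F_h + self.F_w


def critical_wave_speed(fluid: FluidProperties) -> float:
    """Minimum phase speed c = (4 g sigma / rho)**(1/4) of capillary-gravity waves.

    Below c a steadily moving surface disturbance cannot radiate waves,
    so the wave-drag channel is closed; with the default water
    properties c = 0.2313 m/s.
    """
    return (4.0 * fluid.g * fluid.sigma / fluid.rho) ** 0.25


def hydrodynamic_drag(U: float, legs: SupportLegSet, fluid: FluidProperties) -> float:
    """Hydrodynamic drag (N) on a leg set sliding at speed U (m/s).

    Summed per leg as ``1/2 * C_D * rho * U^2 * A``.  A parallel leg
    exposes half its cylinder surface, ``A = (pi D / 2) L``, with the
    Blasius skin-friction coefficient at the per-leg length Reynolds
    number; an orthogonal leg exposes its projection ``A = D L`` with
    the cylinder-crossflow coefficient at the diameter Reynolds number.
    """
    if U < 0:
        raise DomainError(f"speed must be >= 0, got {U!r}")
    if U == 0.0:
        return 0.0
    q = 0.5 * fluid.rho * U * U
    nu = fluid.nu
    parallel = legs.orientation is Orientation.PARALLEL
    total = 0.0
    for L, D in zip(legs.lengths, legs.diameters):
        if L <= 0.0 or D <= 0.0:
            continue
        if parallel:
            re = U * L / nu
            cd = 1.328 / math.sqrt(re)
            area = 0.5 * math.pi * D * L
        else:
            re = U * D / nu
            cd = 1.0 + 10.0 * re ** (-2.0 / 3.0)
            area = D * L
        total += q * cd * area
    return total


def wave_drag(
    N: float,
    legs: SupportLegSet,
    U: float,
    fluid: FluidProperties,
    model: WaveDragModel,
) -> float:
    """Capillary-gravity wave drag (N) on a leg set carrying normal force N.

    Zero at or below the critical speed, and quadratic in the load above
    it (see module docstring for the closed form).  Raises
    :class:`SingularConfigurationError` for a loaded, super-critical
    contact of zero wetted length.
    """
    if N < 0:
        raise DomainError(f"normal force must be >= 0, got {N!r}")
    if U < 0:
        raise DomainError(f"speed must be >= 0, got {U!r}")
    c = critical_wave_speed(fluid)
    if U <= c or N == 0.0 or model.amplitude == 0.0:
        return 0.0
    L = legs.total_wetted_length
    if L <= 0.0:
        raise SingularConfigurationError(
            "wave drag is singular for a loaded, moving contact of zero wetted length"
        )
    x = U / c
    w = model.kernel(x)
    if w < 0:
        raise DomainError(f"wave-drag kernel returned a negative value {w!r} at x={x!r}")
    lc = capillary_length(fluid)
    return (N * N) / (4.0 * math.pi ** 2 * fluid.sigma * L * L) * lc * model.amplitude * w


def total_resistance(
    U: float,
    Na: float,
    Np: float,
    config: SliderConfiguration,
    fluid: FluidProperties,
    model: WaveDragModel,
) -> tuple[ResistanceBreakdown, ResistanceBreakdown]:
    """Anterior and posterior resistance breakdowns at speed U.

    The anterior set feels its own normal force Na, the posterior set
    Np; each contributes hydrodynamic plus wave drag independently.
    """
    if Na < 0 or Np < 0:
        raise DomainError("normal forces must be >= 0")
    ant = ResistanceBreakdown(
        F_h=hydrodynamic_drag(U, config.anterior, fluid),
        F_w=wave_drag(Na, config.anterior, U, fluid, model),
        applied_to=Role.ANTERIOR,
    )
    post = ResistanceBreakdown(
        F_h=hydrodynamic_drag(U, config.posterior, fluid),
        F_w=wave_drag(Np, config.posterior, U, fluid, model),
        applied_to=Role.POSTERIOR,
    )
    return ant, post
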