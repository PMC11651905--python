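"""Domain types shared by every stage of the sliding model.

The model describes a water strider (family Gerridae) that slides
passively on the water surface during the recovery phase of its stride.
The insect is supported by surface tension acting along the wetted
perimeter of its leg contacts.  Two gaits occur in nature:

* **symmetric** — both midlegs stroke together and the body slides on
  two forelegs (anterior support) and two hindlegs (posterior support);
* **asymmetric** — one midleg strokes while the other is extended
  forward as the single anterior support; the forelegs may leave the
  surface entirely.

All quantities are SI internally (kg, m, s, N).  Masses in mg and
lengths in mm are accepted only at the I/O boundary (:mod:`.config`)
and converted exactly once.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "FluidProperties",
    "Orientation",
    "Role",
    "Gait",
    "SupportLegSet",
    "SliderConfiguration",
    "SizeClass",
    "GeometryClass",
    "GEOMETRY_CUTPOINTS",
    "classify_geometry",
    "capillary_length",
    "DomainError",
]


class DomainError(ValueError):
    """An argument lies outside the physical domain of an operation."""


class Orientation(str, enum.Enum):
    """Orientation of a wetted leg relative to the sliding direction."""

    PARALLEL = "parallel"
    ORTHOGONAL = "orthogonal"


class Role(str, enum.Enum):
    """Whether a leg set supports the anterior or the posterior body."""

    ANTERIOR = "anterior"
    POSTERIOR = "posterior"


class Gait(str, enum.Enum):
    SYMMETRIC = "symmetric"
    ASYMMETRIC = "asymmetric"


@dataclass(frozen=True)
class FluidProperties:
    """Bulk properties of the supporting liquid (defaults: clean water).

    Parameters
    ----------
    rho:
        Density in kg m^-3.
    nu:
        Kinematic viscosity in m^2 s^-1.
    sigma:
        Surface tension coefficient in N m^-1.  The default 0.073 makes
        the minimum phase speed of capillary-gravity waves come out at
        0.2313 m s^-1, the threshold below which a moving leg contact
        sheds no wave energy.
    g:
        Gravitational acceleration in m s^-2.
    """

    rho: float = 1000.0
    nu: float = 1.0e-6
    sigma: float = 0.073
    g: float = 9.81

    def __post_init__(self) -> None:
        for name in ("rho", "nu", "sigma", "g"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise DomainError(f"FluidProperties.{name} must be a finite positive number, got {value!r}")


def capillary_length(fluid: FluidProperties) -> float:
    """Capillary length sqrt(sigma / (rho * g)) in metres.

    The natural length scale of surface-tension-dominated deformation of
    the interface; about 2.7 mm for water.  It closes the dimensions of
    the wave-drag kernel (see :func:`striderslide.resistance.wave_drag`).
    """
    return math.sqrt(fluid.sigma / (fluid.rho * fluid.g))


def _as_tuple(values: Sequence[float]) -> tuple[float, ...]:
    return tuple(float(v) for v in values)


@dataclass(frozen=True)
class SupportLegSet:
    """One group of wetted leg contacts acting as a single support.

    ``lengths`` and ``diameters`` are per-leg wetted lengths L and leg
    diameters D in metres.  ``orientation`` states whether the legs lie
    parallel to the sliding direction (the normal posture) or across it
    (the atypical extreme occasionally seen in foreleg tarsi).
    """

    lengths: tuple[float, ...]
    diameters: tuple[float, ...]
    orientation: Orientation = Orientation.PARALLEL
    role: Role = Role.ANTERIOR

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", _as_tuple(self.lengths))
        object.__setattr__(self, "diameters", _as_tuple(self.diameters))
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        object.__setattr__(self, "role", Role(self.role))
        if len(self.lengths) == 0:
            raise DomainError("SupportLegSet needs at least one leg")
        if len(self.lengths) != len(self.diameters):
            raise DomainError(
                f"lengths ({len(self.lengths)}) and diameters ({len(self.diameters)}) must have the same count"
            )
        for L in self.lengths:
            if not (math.isfinite(L) and L >= 0):
                raise DomainError(f"wetted length must be >= 0, got {L!r}")
        for D in self.diameters:
            if not (math.isfinite(D) and D >= 0):
                raise DomainError(f"leg diameter must be >= 0, got {D!r}")

    @property
    def n_legs(self) -> int:
        return len(self.lengths)

    @property
    def total_wetted_length(self) -> float:
        """Sum of per-leg wetted lengths, in metres."""
        return sum(self.lengths)

    @property
    def total_perimeter_term(self) -> float:
        """Sum of (L_i + D_i) over the legs; 2*sigma times this is the
        maximum surface-tension force the set can transmit."""
        return sum(self.lengths) + sum(self.diameters)

    def to_dict(self) -> dict:
        return {
            "lengths": list(self.lengths),
            "diameters": list(self.diameters),
            "orientation": self.orientation.value,
            "role": self.role.value,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SupportLegSet":
        return cls(
            lengths=tuple(data["lengths"]),
            diameters=tuple(data["diameters"]),
            orientation=Orientation(data["orientation"]),
            role=Role(data["role"]),
        )


@dataclass(frozen=True)
class SliderConfiguration:
    """A whole insect in a given gait, ready for the force balance.

    Parameters
    ----------
    mass:
        Body mass m in kg.
    anterior, posterior:
        The two supporting leg sets.  In the symmetric gait the anterior
        set is the two forelegs; in the asymmetric gait it is the single
        forward-extended midleg.  The posterior set is the two hindlegs.
    a, b:
        Horizontal distances (m) from the centre of mass to the centre
        of the anterior (a) and posterior (b) wetted contacts, measured
        along the sliding direction.
    h:
        Height (m) of the centre of mass above the water surface; the
        lever arm through which sliding resistance pitches the body
        tail-up and presses the anterior legs down.
    gait:
        Symmetric or asymmetric; constrains the anterior leg count.
    """

    mass: float
    anterior: SupportLegSet
    posterior: SupportLegSet
    a: float
    b: float
    h: float
    gait: Gait = Gait.SYMMETRIC
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gait", Gait(self.gait))
        if not (math.isfinite(self.mass) and self.mass > 0):
            raise DomainError(f"mass must be > 0, got {self.mass!r}")
        if not (math.isfinite(self.a) and self.a > 0):
            raise DomainError(f"a must be > 0, got {self.a!r}")
        if not (math.isfinite(self.b) and self.b > 0):
            raise DomainError(f"b must be > 0, got {self.b!r}")
        if not (math.isfinite(self.h) and self.h >= 0):
            raise DomainError(f"h must be >= 0, got {self.h!r}")
        if self.gait is Gait.SYMMETRIC and self.anterior.n_legs != 2:
            raise DomainError("symmetric gait requires exactly 2 anterior legs (the forelegs)")
        if self.gait is Gait.ASYMMETRIC and self.anterior.n_legs != 1:
            raise DomainError("asymmetric gait requires exactly 1 anterior leg (the midleg)")
        if self.anterior.role is not Role.ANTERIOR:
            raise DomainError("anterior leg set must have role='anterior'")
        if self.posterior.role is not Role.POSTERIOR:
            raise DomainError("posterior leg set must have role='posterior'")

    def to_dict(self) -> dict:
        return {
            "mass": self.mass,
            "anterior": self.anterior.to_dict(),
            "posterior": self.posterior.to_dict(),
            "a": self.a,
            "b": self.b,
            "h": self.h,
            "gait": self.gait.value,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SliderConfiguration":
        return cls(
            mass=float(data["mass"]),
            anterior=SupportLegSet.from_dict(data["anterior"]),
            posterior=SupportLegSet.from_dict(data["posterior"]),
            a=float(data["a"]),
            b=float(data["b"]),
            h=float(data["h"]),
            gait=Gait(data["gait"]),
            label=str(data.get("label", "")),
        )


@dataclass(frozen=True)
class SizeClass:
    """A body-size class: a mass range (mg) and a sliding-speed range (m/s)."""

    name: str
    mass_range_mg: tuple[float, float]
    velocity_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.mass_range_mg
        if not lo < hi:
            raise DomainError(f"mass range must satisfy min < max, got {self.mass_range_mg}")
        vlo, vhi = self.velocity_range
        if not vlo < vhi:
            raise DomainError(f"velocity range must satisfy min < max, got {self.velocity_range}")

    @property
    def mass_midpoint_mg(self) -> float:
        return 0.5 * (self.mass_range_mg[0] + self.mass_range_mg[1])


@dataclass(frozen=True)
class GeometryClass:
    """A wetted-leg-geometry class: the share of total wetted length on the forelegs."""

    name: str
    foreleg_fraction_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.foreleg_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise DomainError(f"foreleg fraction range must lie inside (0, 1), got {self.foreleg_fraction_range}")

    @property
    def foreleg_fraction_midpoint(self) -> float:
        lo, hi = self.foreleg_fraction_range
        return 0.5 * (lo + hi)


# Cutpoints splitting the three observed, non-overlapping clusters of the
# foreleg share of the total wetted length: short-wetted-foreleg insects
# cluster near 1-3%, the common "standard" geometry near 4-8%, and
# long-wetted-foreleg insects near 12-14%.
GEOMETRY_CUTPOINTS = (0.035, 0.10)


def classify_geometry(foreleg_fraction: float) -> str:
    """Classify a foreleg wetted-length fraction into short / intermediate / long.

    Parameters
    ----------
    foreleg_fraction:
        Wetted foreleg length divided by total wetted length of all six
        legs; must lie strictly inside (0, 1).

    Returns
    -------
    str
        ``"short"`` below 3.5%, ``"intermediate"`` from 3.5% to 10%,
        ``"long"`` at or above 10%.
    """
    if not (isinstance(foreleg_fraction, (int, float)) and math.isfinite(foreleg_fraction)):
        raise DomainError(f"foreleg_fraction must be a finite number, got {foreleg_fraction!r}")
    if not (0.0 < foreleg_fraction < 1.0):
        raise DomainError(f"foreleg_fraction must lie in (0, 1), got {foreleg_fraction!r}")
    lo, hi = GEOMETRY_CUTPOINTS
    if foreleg_fraction < lo:
        return "short"
    if foreleg_fraction < hi:
        return "intermediate"
    return "long"
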