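"""Synthetic morphologies and stride events.

This module is the study-condition generator: it emulates the five
body-size classes (printed mass and sliding-speed ranges) and the three
wetted-leg-geometry classes (printed foreleg fractions) so that every
downstream stage is testable without any external data.

The per-class wetted lengths, leg diameters and lever arms are
*calibrated defaults*, not measured specimen values: they follow the
known allometry (total wetted length grows with class mass) and are
fixed once so that the size-class x geometry x gait floatability
pattern of the study system is reproduced.  Within a class, wetted
lengths scale with the cube root of mass, keeping within-class
allometry mild; the cross-class table carries the real allometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    DomainError,
    FluidProperties,
    Gait,
    GeometryClass,
    Orientation,
    Role,
    SizeClass,
    SliderConfiguration,
    SupportLegSet,
)
from .dynamics import StopCriteria, simulate_slide
from .resistance import WaveDragModel, critical_wave_speed

__all__ = [
    "SIZE_CLASSES",
    "GEOMETRY_CLASSES",
    "SCENARIOS",
    "MorphologyDefaults",
    "StrideEvent",
    "size_class",
    "geometry_class",
    "build_configuration",
    "default_configuration",
    "default_gait_pair",
    "generate_morphology",
    "generate_stride_events",
    "event_summaries",
]

SCENARIOS = ("parallel_full", "parallel_minimal_midleg", "orthogonal")


@dataclass(frozen=True)
class MorphologyDefaults:
    """Calibrated per-size-class defaults (SI units)."""

    body_length: float  # m
    total_wetted_length: float  # m, at the class mass midpoint
    leg_diameter: float  # m
    h: float  # m, COM height above the surface


# Size classes: printed mass ranges (mg) and observed sliding-speed
# ranges (m/s) for the five study size classes, smallest to largest.
SIZE_CLASSES: dict[str, SizeClass] = {
    "G_latiabdominis": SizeClass("G_latiabdominis", (12.0, 32.0), (0.0, 1.0)),
    "A_paludum": SizeClass("A_paludum", (35.0, 72.0), (0.0, 1.5)),
    "P_tigrina": SizeClass("P_tigrina", (83.0, 144.0), (0.0, 2.5)),
    "G_gigas_female": SizeClass("G_gigas_female", (217.0, 318.0), (0.0, 2.5)),
    "G_gigas_male": SizeClass("G_gigas_male", (316.0, 511.0), (0.0, 2.5)),
}

# Calibrated defaults per size class.  Body lengths sit at the midpoints
# of the recorded ranges; wetted lengths / diameters / COM heights grow
# with class size.
MORPHOLOGY_DEFAULTS: dict[str, MorphologyDefaults] = {
    "G_latiabdominis": MorphologyDefaults(12.3e-3, 40e-3, 0.15e-3, 3.0e-3),
    "A_paludum": MorphologyDefaults(15.0e-3, 70e-3, 0.20e-3, 4.0e-3),
    "P_tigrina": MorphologyDefaults(17.0e-3, 110e-3, 0.25e-3, 5.0e-3),
    "G_gigas_female": MorphologyDefaults(32.6e-3, 220e-3, 0.35e-3, 6.0e-3),
    "G_gigas_male": MorphologyDefaults(36.0e-3, 260e-3, 0.40e-3, 6.0e-3),
}

# Lever arms as fractions of body length: the anterior contact sits
# further forward when the support is the forward-extended midleg.
A_FRACTION_FORELEG = 0.30
A_FRACTION_MIDLEG = 0.45
B_FRACTION = 0.30

GEOMETRY_CLASSES: dict[str, GeometryClass] = {
    "short": GeometryClass("short", (0.01, 0.03)),
    "intermediate": GeometryClass("intermediate", (0.04, 0.08)),
    "long": GeometryClass("long", (0.12, 0.14)),
}

# Representative split of the total wetted length over (fore, mid, hind)
# legs per geometry class, i.e. the calibrated stand-in for the
# representative species of each class.  The foreleg share is also the
# default foreleg fraction used by the phase sweep; midleg and hindleg
# shares are rescaled when a different foreleg fraction is sampled so
# the three always sum to 1.
GEOMETRY_SPLITS: dict[str, tuple[float, float, float]] = {
    "short": (0.02, 0.40, 0.58),
    "intermediate": (0.05, 0.40, 0.55),
    "long": (0.13, 0.42, 0.45),
}


def size_class(name: str) -> SizeClass:
    try:
        return SIZE_CLASSES[name]
    except KeyError:
        raise DomainError(f"unknown size class {name!r}; known: {sorted(SIZE_CLASSES)}") from None


def geometry_class(name: str) -> GeometryClass:
    try:
        return GEOMETRY_CLASSES[name]
    except KeyError:
        raise DomainError(f"unknown geometry class {name!r}; known: {sorted(GEOMETRY_CLASSES)}") from None


def _leg_fractions(geometry: str, foreleg_fraction: float) -> tuple[float, float, float]:
    f0, m0, h0 = GEOMETRY_SPLITS[geometry]
    rest = 1.0 - foreleg_fraction
    scale = rest / (m0 + h0)
    return foreleg_fraction, m0 * scale, h0 * scale


def build_configuration(
    geometry: str,
    size: str,
    gait: Gait | str,
    *,
    mass_kg: float | None = None,
    foreleg_fraction: float | None = None,
    scenario: str = "parallel_full",
    label: str = "",
) -> SliderConfiguration:
    """Assemble one slider from the calibrated class defaults.

    ``mass_kg`` defaults to the class midpoint and ``foreleg_fraction``
    to the geometry midpoint.  The total wetted length is the class
    default scaled by ``(mass / class midpoint)**(1/3)``.

    Scenarios reflect the empirically observed variation of the anterior
    support:

    * ``parallel_full`` — anterior legs parallel, full wetted lengths
      (foreleg tarsus in symmetric gait; midleg tarsus+tibia in
      asymmetric gait);
    * ``parallel_minimal_midleg`` — the asymmetric anterior midleg wets
      only half its tibiotarsal segment (a quarter of the midleg), the
      minimum seen in medium-sized sliders; symmetric gait unchanged;
    * ``orthogonal`` — the symmetric-gait forelegs lie across the
      sliding direction (the atypical extreme); the asymmetric midleg
      support is always held parallel, so asymmetric configurations are
      unchanged.
    """
    gait = Gait(gait)
    if scenario not in SCENARIOS:
        raise DomainError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")
    sc = size_class(size)
    gc = geometry_class(geometry)
    defaults = MORPHOLOGY_DEFAULTS[size]

    if mass_kg is None:
        mass_kg = sc.mass_midpoint_mg * 1e-6
    if foreleg_fraction is None:
        foreleg_fraction = GEOMETRY_SPLITS[geometry][0]

    mid_mass_kg = sc.mass_midpoint_mg * 1e-6
    total_wetted = defaults.total_wetted_length * (mass_kg / mid_mass_kg) ** (1.0 / 3.0)
    f_fore, f_mid, f_hind = _leg_fractions(geometry, foreleg_fraction)
    D = defaults.leg_diameter
    BL = defaults.body_length

    hind = SupportLegSet(
        lengths=(f_hind * total_wetted / 2.0,) * 2,
        diameters=(D, D),
        orientation=Orientation.PARALLEL,
        role=Role.POSTERIOR,
    )

    if gait is Gait.SYMMETRIC:
        orientation = Orientation.ORTHOGONAL if scenario == "orthogonal" else Orientation.PARALLEL
        anterior = SupportLegSet(
            lengths=(f_fore * total_wetted / 2.0,) * 2,
            diameters=(D, D),
            orientation=orientation,
            role=Role.ANTERIOR,
        )
        a = A_FRACTION_FORELEG * BL
    else:
        midleg_wetted = f_mid * total_wetted / 2.0  # one midleg, tarsus+tibia
        if scenario == "parallel_minimal_midleg":
            midleg_wetted *= 0.5  # half the tibiotarsal segment
        anterior = SupportLegSet(
            lengths=(midleg_wetted,),
            diameters=(D,),
            orientation=Orientation.PARALLEL,
            role=Role.ANTERIOR,
        )
        a = A_FRACTION_MIDLEG * BL

    return SliderConfiguration(
        mass=mass_kg,
        anterior=anterior,
        posterior=hind,
        a=a,
        b=B_FRACTION * BL,
        h=defaults.h,
        gait=gait,
        label=label or f"{size}/{geometry}/{gait.value}/{scenario}",
    )


def default_configuration(
    geometry: str,
    size: str,
    gait: Gait | str,
    scenario: str = "parallel_full",
) -> SliderConfiguration:
    """Class-midpoint slider for the given geometry, size and gait."""
    return build_configuration(geometry, size, gait, scenario=scenario)


def default_gait_pair(size: str = "A_paludum") -> tuple[SliderConfiguration, SliderConfiguration]:
    """Matched-mass symmetric / asymmetric pair for gait comparison.

    The symmetric slider rides on its full foreleg tarsi; the
    asymmetric one on the minimal wetted midleg (half the tibiotarsal
    segment), the support length actually observed in medium-sized
    sliders using the asymmetric gait.
    """
    sym = build_configuration("intermediate", size, Gait.SYMMETRIC)
    asym = build_configuration(
        "intermediate", size, Gait.ASYMMETRIC, scenario="parallel_minimal_midleg"
    )
    return sym, asym


def generate_morphology(
    geometry: str,
    size: str,
    seed: int,
    n: int,
    *,
    gait: Gait | str = Gait.SYMMETRIC,
    scenario: str = "parallel_full",
) -> list[SliderConfiguration]:
    """Draw ``n`` sliders with mass and foreleg fraction uniform over the class ranges.

    Deterministic for a given seed.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    sc = size_class(size)
    gc = geometry_class(geometry)
    rng = np.random.default_rng(seed)
    masses_mg = rng.uniform(*sc.mass_range_mg, size=n)
    fractions = rng.uniform(*gc.foreleg_fraction_range, size=n)
    return [
        build_configuration(
            geometry,
            size,
            gait,
            mass_kg=float(m) * 1e-6,
            foreleg_fraction=float(f),
            scenario=scenario,
            label=f"{size}/{geometry}#{i}",
        )
        for i, (m, f) in enumerate(zip(masses_mg, fractions))
    ]


# ---------------------------------------------------------------------------
# Stride events


@dataclass(frozen=True)
class StrideEvent:
    """One recovery-phase event: gait, launch speed, and slide outcome."""

    gait: str  # "symmetric_slide" | "asymmetric_slide" | "leap"
    U0: float
    distance: float
    duration: float

    def __post_init__(self) -> None:
        if self.U0 < 0 or self.distance < 0 or self.duration < 0:
            raise DomainError("U0, distance and duration must be >= 0")


EVENT_GAITS = ("symmetric_slide", "asymmetric_slide", "leap")

# Per-gait lognormal launch-speed parameters (median m/s, log-sd).
# Asymmetric slides start mostly above the wave-making threshold
# (lower quartile ~0.26 m/s); leaps follow fast strokes (> 0.5 m/s).
DEFAULT_VELOCITY_PARAMS: dict[str, tuple[float, float]] = {
    "symmetric_slide": (0.25, 0.70),
    "asymmetric_slide": (0.40, 0.65),
    "leap": (0.65, 0.30),
}

# Observed event mix: of 236 recovery events in the medium-sized study
# species, 86 were asymmetric slides and leaps were the rarest mode.
DEFAULT_GAIT_MIX = (100 / 236, 86 / 236, 50 / 236)


def generate_stride_events(
    n: int,
    seed: int,
    *,
    mix: Sequence[float] = DEFAULT_GAIT_MIX,
    velocity_params: dict[str, tuple[float, float]] | None = None,
    fluid: FluidProperties | None = None,
    model: WaveDragModel | None = None,
    dt: float = 1e-3,
    stop: StopCriteria | None = None,
) -> list[StrideEvent]:
    """Draw ``n`` stride events with per-gait lognormal launch speeds.

    Gaits are drawn from ``mix`` (symmetric slide, asymmetric slide,
    leap); sliding distance and duration are then filled by simulating
    the slide on the default medium-class morphology of the matching
    gait (leaps use the symmetric-gait morphology).  Deterministic for
    a given seed.
    """
    if n < 0:
        raise DomainError(f"n must be >= 0, got {n}")
    mix = tuple(float(p) for p in mix)
    if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
        raise DomainError(f"gait mix must be 3 non-negative proportions summing to 1, got {mix}")
    if n == 0:
        return []
    params = dict(DEFAULT_VELOCITY_PARAMS)
    if velocity_params:
        unknown = set(velocity_params) - set(EVENT_GAITS)
        if unknown:
            raise DomainError(f"unknown gait keys in velocity_params: {sorted(unknown)}")
        params.update(velocity_params)
    fluid = fluid or FluidProperties()
    model = model or WaveDragModel()
    stop = stop or StopCriteria()

    sym, asym = default_gait_pair()
    config_for = {
        "symmetric_slide": sym,
        "asymmetric_slide": asym,
        "leap": sym,
    }

    rng = np.random.default_rng(seed)
    gaits = rng.choice(EVENT_GAITS, size=n, p=mix)
    events = []
    for g in gaits:
        median, log_sd = params[str(g)]
        u0 = float(np.exp(rng.normal(math.log(median), log_sd)))
        traj = simulate_slide(config_for[str(g)], u0, fluid, model, dt=dt, stop=stop)
        events.append(StrideEvent(gait=str(g), U0=u0, distance=traj.distance, duration=traj.duration))
    return events


def event_summaries(
    events: Iterable[StrideEvent],
    fluid: FluidProperties | None = None,
) -> dict[str, dict[str, float]]:
    """Per-gait summary: launch-speed quartiles, median slide outcome,
    and the fraction of launches above the critical wave speed.

    Quartiles follow the linear-interpolation convention between order
    statistics (numpy's default), and are invariant to event order.
    """
    events = list(events)
    if not events:
        raise DomainError("event_summaries requires at least one event")
    fluid = fluid or FluidProperties()
    c = critical_wave_speed(fluid)
    out: dict[str, dict[str, float]] = {}
    for g in EVENT_GAITS:
        sub = [e for e in events if e.gait == g]
        if not sub:
            continue
        u0 = np.array([e.U0 for e in sub])
        q1, q2, q3 = np.percentile(u0, [25, 50, 75])
        out[g] = {
            "n": float(len(sub)),
            "U0_q1": float(q1),
            "U0_median": float(q2),
            "U0_q3": float(q3),
            "distance_median": float(np.median([e.distance for e in sub])),
            "duration_median": float(np.median([e.duration for e in sub])),
            "fraction_above_c": float(np.mean(u0 > c)),
        }
    return out
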