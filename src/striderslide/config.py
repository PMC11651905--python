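"""Configuration handling and file writers.

JSON is the single configuration format (no YAML dialects): sections
``fluid``, ``slider`` and ``simulation``, all optional, all strictly
parsed — unknown keys are rejected by name.  Unit conversion happens
here and only here: masses and lengths may be given as quantity strings
("20 mg", "4.5 mm") or as bare numbers already in SI.

CSV writers emit a fixed column order with '.' decimal, ',' separator,
a header row and LF line endings, so outputs are bit-stable across
platforms.  Every run directory gets a JSON metadata sidecar recording
the seed, package version and a hash of the effective configuration.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd

from .core import (
    DomainError,
    FluidProperties,
    Gait,
    Orientation,
    Role,
    SliderConfiguration,
    SupportLegSet,
)
from .dynamics import StopCriteria, Trajectory
from .resistance import DEFAULT_WAVE_AMPLITUDE, KERNELS, WaveDragModel
from .synthetic import StrideEvent

__all__ = [
    "ConfigError",
    "RunConfig",
    "SimulationSettings",
    "parse_quantity",
    "read_config",
    "write_trajectory_csv",
    "write_events_csv",
    "write_morphology_csv",
    "read_morphology_csv",
    "write_metadata",
]

PACKAGE_VERSION = "0.1.0"


class ConfigError(DomainError):
    """A configuration file or value is malformed."""


_MASS_UNITS = {"kg": 1.0, "g": 1e-3, "mg": 1e-6}
_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6}
_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Z]+)\s*$")


def parse_quantity(value: Any, kind: str) -> float:
    """Convert a config value to SI.

    ``kind`` is ``"mass"`` or ``"length"``.  Bare numbers are taken to
    be SI already (kg / m); strings must carry a recognised unit.
    """
    units = _MASS_UNITS if kind == "mass" else _LENGTH_UNITS
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        m = _QUANTITY_RE.match(value)
        if not m:
            raise ConfigError(f"cannot parse {kind} quantity {value!r}")
        number, unit = m.groups()
        if unit not in units:
            raise ConfigError(f"unknown {kind} unit {unit!r} in {value!r}; known: {sorted(units)}")
        try:
            return float(number) * units[unit]
        except ValueError:
            raise ConfigError(f"cannot parse number in {kind} quantity {value!r}") from None
    raise ConfigError(f"{kind} value must be a number or a quantity string, got {value!r}")


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass(frozen=True)
class SimulationSettings:
    U0: float = 0.5
    dt: float = 1e-4
    U_stop: float = 0.01
    t_max: float = 2.0
    kernel: str = "peaked"
    amplitude: float = DEFAULT_WAVE_AMPLITUDE
    n_mass: int = 12
    n_velocity: int = 25
    seed: int = 0

    def wave_model(self) -> WaveDragModel:
        return WaveDragModel.from_name(self.kernel, self.amplitude)

    def stop_criteria(self) -> StopCriteria:
        return StopCriteria(U_stop=self.U_stop, t_max=self.t_max)


@dataclass(frozen=True)
class RunConfig:
    fluid: FluidProperties = field(default_factory=FluidProperties)
    slider: SliderConfiguration | None = None
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    raw: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _parse_fluid(section: dict) -> FluidProperties:
    _check_keys(section, {"rho", "nu", "sigma", "g"}, "fluid")
    try:
        return FluidProperties(**{k: float(v) for k, v in section.items()})
    except DomainError as exc:
        raise ConfigError(str(exc)) from None


def _parse_leg_set(section: dict, role: Role, where: str) -> SupportLegSet:
    _check_keys(section, {"lengths", "diameters", "orientation"}, where)
    for key in ("lengths", "diameters"):
        if key not in section:
            raise ConfigError(f"{where} is missing required key {key!r}")
    try:
        return SupportLegSet(
            lengths=tuple(parse_quantity(v, "length") for v in section["lengths"]),
            diameters=tuple(parse_quantity(v, "length") for v in section["diameters"]),
            orientation=Orientation(section.get("orientation", "parallel")),
            role=role,
        )
    except (DomainError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from None


def _parse_slider(section: dict) -> SliderConfiguration:
    _check_keys(
        section,
        {"mass", "gait", "anterior", "posterior", "a", "b", "h", "label"},
        "slider",
    )
    for key in ("mass", "anterior", "posterior", "a", "b", "h"):
        if key not in section:
            raise ConfigError(f"slider is missing required key {key!r}")
    try:
        return SliderConfiguration(
            mass=parse_quantity(section["mass"], "mass"),
            anterior=_parse_leg_set(section["anterior"], Role.ANTERIOR, "slider.anterior"),
            posterior=_parse_leg_set(section["posterior"], Role.POSTERIOR, "slider.posterior"),
            a=parse_quantity(section["a"], "length"),
            b=parse_quantity(section["b"], "length"),
            h=parse_quantity(section["h"], "length"),
            gait=Gait(section.get("gait", "symmetric")),
            label=str(section.get("label", "")),
        )
    except (DomainError, ValueError) as exc:
        raise ConfigError(f"slider: {exc}") from None


def _parse_simulation(section: dict) -> SimulationSettings:
    allowed = {"U0", "dt", "U_stop", "t_max", "kernel", "amplitude", "n_mass", "n_velocity", "seed"}
    _check_keys(section, allowed, "simulation")
    kwargs: dict[str, Any] = {}
    for key in allowed & set(section):
        value = section[key]
        if key in ("n_mass", "n_velocity", "seed"):
            kwargs[key] = int(value)
        elif key == "kernel":
            if value not in KERNELS:
                raise ConfigError(f"unknown wave-drag kernel {value!r}; known: {sorted(KERNELS)}")
            kwargs[key] = str(value)
        else:
            kwargs[key] = float(value)
    settings = SimulationSettings(**kwargs)
    if settings.dt <= 0:
        raise ConfigError(f"simulation.dt must be > 0, got {settings.dt}")
    if settings.amplitude < 0:
        raise ConfigError(f"simulation.amplitude must be >= 0, got {settings.amplitude}")
    return settings


def parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a JSON object")
    _check_keys(data, {"fluid", "slider", "simulation"}, "config root")
    fluid = _parse_fluid(data.get("fluid", {}))
    slider = _parse_slider(data["slider"]) if "slider" in data else None
    simulation = _parse_simulation(data.get("simulation", {}))
    return RunConfig(fluid=fluid, slider=slider, simulation=simulation, raw=data)


def read_config(path: str | Path) -> RunConfig:
    """Read and strictly validate a JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config file {path} is not valid JSON: {exc}") from None
    return parse_config(data)


def write_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config.raw, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# CSV writers

TRAJECTORY_COLUMNS = ["t_s", "U_mps", "x_m", "dec_mps2", "Na_N", "Np_N", "Ra_N", "Rp_N", "breaks"]


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    rows = []
    for i in range(len(traj.times)):
        sol = traj.statics_per_step[i]
        rows.append(
            {
                "t_s": traj.times[i],
                "U_mps": traj.velocities[i],
                "x_m": traj.positions[i],
                "dec_mps2": traj.decelerations[i],
                "Na_N": sol.Na if sol else 0.0,
                "Np_N": sol.Np if sol else 0.0,
                "Ra_N": sol.Ra if sol else 0.0,
                "Rp_N": sol.Rp if sol else 0.0,
                "breaks": bool(sol.breaks) if sol else False,
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False, lineterminator="\n")
    return path


EVENT_COLUMNS = ["gait", "U0_mps", "distance_m", "duration_s"]


def write_events_csv(events: Iterable[StrideEvent], path: str | Path) -> Path:
    rows = [
        {"gait": e.gait, "U0_mps": e.U0, "distance_m": e.distance, "duration_s": e.duration}
        for e in events
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False, lineterminator="\n")
    return path


MORPHOLOGY_COLUMNS = [
    "id",
    "species_label",
    "mass_mg",
    "foreleg_wetted_mm",
    "midleg_wetted_mm",
    "hindleg_wetted_mm",
    "leg_diameter_mm",
    "a_mm",
    "b_mm",
    "h_mm",
]


def write_morphology_csv(rows: Iterable[dict], path: str | Path) -> Path:
    """Write a morphology table; rows must carry the standard columns
    (per-leg wetted lengths and lever arms in mm, mass in mg)."""
    df = pd.DataFrame(list(rows))
    missing = set(MORPHOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"morphology rows are missing column(s): {sorted(missing)}")
    path = Path(path)
    df[MORPHOLOGY_COLUMNS].to_csv(path, index=False, lineterminator="\n")
    return path


def read_morphology_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"morphology file not found: {path}")
    df = pd.read_csv(path)
    missing = set(MORPHOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"morphology table is missing column(s): {sorted(missing)}")
    return df


def morphology_row_to_configuration(row: pd.Series | dict, gait: Gait | str = Gait.SYMMETRIC) -> SliderConfiguration:
    """Build a slider from one morphology-table row (mg / mm units).

    The symmetric gait uses two forelegs of ``foreleg_wetted_mm`` each;
    the asymmetric gait one midleg of ``midleg_wetted_mm``; the
    posterior is always two hindlegs of ``hindleg_wetted_mm`` each.
    """
    gait = Gait(gait)
    D = float(row["leg_diameter_mm"]) * 1e-3
    hind = SupportLegSet(
        lengths=(float(row["hindleg_wetted_mm"]) * 1e-3,) * 2,
        diameters=(D, D),
        role=Role.POSTERIOR,
    )
    if gait is Gait.SYMMETRIC:
        anterior = SupportLegSet(
            lengths=(float(row["foreleg_wetted_mm"]) * 1e-3,) * 2,
            diameters=(D, D),
            role=Role.ANTERIOR,
        )
    else:
        anterior = SupportLegSet(
            lengths=(float(row["midleg_wetted_mm"]) * 1e-3,),
            diameters=(D,),
            role=Role.ANTERIOR,
        )
    return SliderConfiguration(
        mass=float(row["mass_mg"]) * 1e-6,
        anterior=anterior,
        posterior=hind,
        a=float(row["a_mm"]) * 1e-3,
        b=float(row["b_mm"]) * 1e-3,
        h=float(row["h_mm"]) * 1e-3,
        gait=gait,
        label=str(row.get("species_label", "")),
    )


def write_metadata(outdir: str | Path, config: RunConfig, seed: int, extra: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "package": "striderslide",
        "version": PACKAGE_VERSION,
        "seed": seed,
        "config_hash": config.content_hash(),
    }
    if extra:
        meta.update(extra)
    path = outdir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path
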