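"""Floatability phase-diagram sweep.

Sweeps geometry classes x size classes x gaits x anterior-support
scenarios, solving the support balance on a (mass, velocity) grid per
situation and recording each point in the (anterior wetted perimeter,
Na) plane together with its meniscus-breaking flag.  The diagonal
``Na = 2 sigma (La + D)`` separates floating from breaking.

Each situation is classified by exact set operations on the break
flags (no tunable fraction cutoffs):

* ``always_floats``  — no grid point breaks;
* ``always_breaks``  — every grid point breaks, including at rest;
* ``breaks_when_fast`` — anything in between (the break region is the
  high-load corner of the grid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import DomainError, FluidProperties, Gait
from .resistance import WaveDragModel
from .statics import solve_support_forces
from .synthetic import (
    GEOMETRY_CLASSES,
    GEOMETRY_SPLITS,
    SCENARIOS,
    SIZE_CLASSES,
    build_configuration,
    size_class,
)

__all__ = [
    "GridSpec",
    "PhasePoint",
    "SituationResult",
    "evaluate_situation",
    "build_floatability_table",
    "summary_table",
    "export_results",
]


@dataclass(frozen=True)
class GridSpec:
    """Sweep resolution: mass and velocity points per situation."""

    n_mass: int = 12
    n_velocity: int = 25

    def __post_init__(self) -> None:
        if self.n_mass < 1 or self.n_velocity < 1:
            raise DomainError("grid must have at least one mass and one velocity point")


class PhasePoint(NamedTuple):
    mass_kg: float
    U: float
    perimeter: float  # 2 * sum(L + D) over the anterior legs, m
    Na: float
    critical: float  # 2 * sigma * sum(L + D), N
    breaks: bool
    converged: bool


@dataclass(frozen=True)
class SituationResult:
    geometry: str
    size: str
    gait: Gait
    scenario: str
    points: tuple[PhasePoint, ...]

    @property
    def classification(self) -> str:
        flags = [p.breaks for p in self.points]
        if not any(flags):
            return "always_floats"
        if all(flags):
            return "always_breaks"
        return "breaks_when_fast"

    @property
    def break_fraction(self) -> float:
        return sum(p.breaks for p in self.points) / len(self.points)


def evaluate_situation(
    geometry: str,
    size: str,
    gait: Gait | str,
    scenario: str,
    fluid: FluidProperties,
    model: WaveDragModel,
    *,
    grid: GridSpec | None = None,
    seed: int = 0,
    sample_fractions: bool = False,
) -> SituationResult:
    """Sweep one situation over its class's (mass, velocity) grid.

    The morphology at each grid point comes from the calibrated
    defaults at the representative (class-midpoint) foreleg fraction;
    with ``sample_fractions=True`` the fraction is instead drawn
    uniformly over the geometry class's range, deterministically for
    the given seed.  Solver infeasibility at a point is recorded (a
    runaway anterior load certainly breaks), never raised.
    """
    gait = Gait(gait)
    grid = grid or GridSpec()
    sc = size_class(size)
    masses_mg = np.linspace(*sc.mass_range_mg, grid.n_mass)
    speeds = np.linspace(*sc.velocity_range, grid.n_velocity)
    rng = np.random.default_rng(seed)
    if sample_fractions:
        lo, hi = GEOMETRY_CLASSES[geometry].foreleg_fraction_range
        fractions = rng.uniform(lo, hi, size=grid.n_mass)
    else:
        fractions = np.full(grid.n_mass, GEOMETRY_SPLITS[geometry][0])

    points: list[PhasePoint] = []
    for m_mg, frac in zip(masses_mg, fractions):
        config = build_configuration(
            geometry,
            size,
            gait,
            mass_kg=float(m_mg) * 1e-6,
            foreleg_fraction=float(frac),
            scenario=scenario,
        )
        perimeter = 2.0 * config.anterior.total_perimeter_term
        warm = None
        for U in speeds:
            sol = solve_support_forces(config, float(U), fluid, model, warm_start=warm)
            if sol.converged:
                warm = sol.Na
            points.append(
                PhasePoint(
                    mass_kg=float(m_mg) * 1e-6,
                    U=float(U),
                    perimeter=perimeter,
                    Na=sol.Na,
                    critical=sol.critical_force,
                    breaks=sol.breaks,
                    converged=sol.converged,
                )
            )
    return SituationResult(geometry=geometry, size=size, gait=gait, scenario=scenario, points=tuple(points))


def build_floatability_table(
    fluid: FluidProperties,
    model: WaveDragModel,
    *,
    grid: GridSpec | None = None,
    seed: int = 0,
    scenarios: Sequence[str] = SCENARIOS,
) -> list[SituationResult]:
    """Evaluate the full cross of geometries x sizes x gaits x scenarios.

    Per scenario this is 30 situations (3 geometries x 5 size classes
    x 2 gaits); the default three scenarios give 90 in total.
    """
    results = []
    for scenario in scenarios:
        if scenario not in SCENARIOS:
            raise DomainError(f"unknown scenario {scenario!r}; known: {SCENARIOS}")
        for geometry in GEOMETRY_CLASSES:
            for size in SIZE_CLASSES:
                for gait in (Gait.SYMMETRIC, Gait.ASYMMETRIC):
                    results.append(
                        evaluate_situation(
                            geometry, size, gait, scenario, fluid, model, grid=grid, seed=seed
                        )
                    )
    return results


def summary_table(results: Sequence[SituationResult]) -> pd.DataFrame:
    """One row per situation: classification and break fraction."""
    if not results:
        raise DomainError("no situations to summarise")
    return pd.DataFrame(
        {
            "geometry": r.geometry,
            "size": r.size,
            "gait": r.gait.value,
            "scenario": r.scenario,
            "classification": r.classification,
            "break_fraction": r.break_fraction,
        }
        for r in results
    )


def export_results(results: Sequence[SituationResult], path: str | Path) -> dict[str, Path]:
    """Write the per-point CSV and the JSON classification summary.

    Returns the written paths.  Output is bit-stable for a given input:
    fixed column order, '.' decimal, ',' separator, LF line endings.
    """
    results = list(results)
    if not results:
        raise DomainError("export_results: no results to write")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for r in results:
        for p in r.points:
            rows.append(
                {
                    "geometry": r.geometry,
                    "size": r.size,
                    "gait": r.gait.value,
                    "scenario": r.scenario,
                    "mass_mg": p.mass_kg * 1e6,
                    "U_mps": p.U,
                    "perimeter_m": p.perimeter,
                    "Na_N": p.Na,
                    "critical_N": p.critical,
                    "breaks": p.breaks,
                }
            )
    csv_path = path / "phase_points.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False, lineterminator="\n")

    summary = {
        f"{r.scenario}/{r.geometry}/{r.size}/{r.gait.value}": {
            "classification": r.classification,
            "break_fraction": r.break_fraction,
            "n_points": len(r.points),
        }
        for r in results
    }
    json_path = path / "floatability_summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"points_csv": csv_path, "summary_json": json_path}
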