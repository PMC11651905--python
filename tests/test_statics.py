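"""Support-force balance: lever limits, conservation, oracle agreement."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from striderslide import (
    DomainError,
    Gait,
    Role,
    SliderConfiguration,
    SupportLegSet,
    WaveDragModel,
    check_floatability,
    critical_support_force,
    critical_wave_speed,
    default_configuration,
    generate_morphology,
    saturating_kernel,
    solve_support_forces,
    total_resistance,
)


class TestCriticalSupportForce:
    def test_single_leg_arithmetic(self):
        legs = SupportLegSet(lengths=(0.010,), diameters=(3.0e-4,))
        # 2 * 0.073 * (0.010 + 0.0003) = 1.5038e-3 N
        assert critical_support_force(legs, 0.073) == pytest.approx(1.5038e-3, rel=1e-6)

    def test_zero_length_degenerates_to_diameters(self):
        legs = SupportLegSet(lengths=(0.0, 0.0), diameters=(3e-4, 3e-4))
        assert critical_support_force(legs, 0.073) == pytest.approx(2 * 0.073 * 6e-4, rel=1e-12)

    def test_linear_in_perimeter(self):
        legs = SupportLegSet(lengths=(0.01, 0.02), diameters=(2e-4, 2e-4))
        doubled = SupportLegSet(lengths=(0.02, 0.04), diameters=(4e-4, 4e-4))
        assert critical_support_force(doubled, 0.073) == pytest.approx(
            2 * critical_support_force(legs, 0.073), rel=1e-12
        )


class TestStaticLimit:
    def test_lever_rule_at_rest(self, fluid, model, medium_symmetric):
        sol = solve_support_forces(medium_symmetric, 0.0, fluid, model)
        mg = medium_symmetric.mass * fluid.g
        a, b = medium_symmetric.a, medium_symmetric.b
        assert sol.converged
        assert sol.Ra == 0.0 and sol.Rp == 0.0
        assert sol.Na == pytest.approx(mg * b / (a + b), abs=1e-15)
        assert sol.Np == pytest.approx(mg * a / (a + b), abs=1e-15)

    def test_equal_arms_split_weight_evenly(self, fluid, model):
        legs_a = SupportLegSet(lengths=(2e-3, 2e-3), diameters=(2e-4, 2e-4), role=Role.ANTERIOR)
        legs_p = SupportLegSet(lengths=(0.02, 0.02), diameters=(2e-4, 2e-4), role=Role.POSTERIOR)
        cfg = SliderConfiguration(
            mass=5e-5, anterior=legs_a, posterior=legs_p, a=5e-3, b=5e-3, h=4e-3, gait=Gait.SYMMETRIC
        )
        sol = solve_support_forces(cfg, 0.0, fluid, model)
        assert sol.Na == pytest.approx(sol.Np, rel=1e-12)
        assert sol.Na == pytest.approx(0.5 * cfg.mass * fluid.g, rel=1e-12)

    def test_negative_speed_rejected(self, fluid, model, medium_symmetric):
        with pytest.raises(DomainError):
            solve_support_forces(medium_symmetric, -0.1, fluid, model)


def _bisection_oracle(config, U, fluid, model):
    """Independent 1-D root bracketing on g(Na) = Na - (mgb + h R(Na))/(a+b)."""
    mg = config.mass * fluid.g

    def g(na):
        ant, post = total_resistance(U, max(na, 0.0), max(mg - na, 0.0), config, fluid, model)
        return na - (mg * config.b + config.h * (ant.total + post.total)) / (config.a + config.b)

    return brentq(g, 0.0, mg, xtol=1e-15, rtol=1e-15)


def _oracle_sweep_configs(fluid):
    """Seeded random configurations in the convergent regime."""
    c = critical_wave_speed(fluid)
    rng = np.random.default_rng(42)
    cases = []
    sizes = ["G_latiabdominis", "A_paludum", "P_tigrina", "G_gigas_female", "G_gigas_male"]
    # asymmetric sliders at any speed of their class range
    for i, size in enumerate(sizes):
        for geometry in ("short", "intermediate", "long"):
            for cfg in generate_morphology(geometry, size, seed=100 + i, n=4, gait=Gait.ASYMMETRIC):
                cases.append((cfg, float(rng.uniform(0.0, 1.5))))
    # symmetric long-foreleg sliders (weak wave feedback) at speed
    for i, size in enumerate(sizes):
        for cfg in generate_morphology("long", size, seed=200 + i, n=4, gait=Gait.SYMMETRIC):
            cases.append((cfg, float(rng.uniform(0.0, 1.5))))
    # symmetric short/intermediate sliders below the wave threshold
    for i, size in enumerate(sizes):
        for cfg in generate_morphology("intermediate", size, seed=300 + i, n=4, gait=Gait.SYMMETRIC):
            cases.append((cfg, float(rng.uniform(0.0, 0.99 * c))))
    return cases[:100]


class TestSolverAgreement:
    def test_fixed_point_matches_bisection_oracle(self, fluid, model):
        cases = _oracle_sweep_configs(fluid)
        assert len(cases) == 100
        for cfg, U in cases:
            sol = solve_support_forces(cfg, U, fluid, model)
            assert sol.converged, f"{cfg.label} at U={U}"
            oracle = _bisection_oracle(cfg, U, fluid, model)
            assert abs(sol.Na - oracle) <= 1e-9

    def test_weight_conservation(self, fluid, model):
        for cfg, U in _oracle_sweep_configs(fluid)[:25]:
            sol = solve_support_forces(cfg, U, fluid, model)
            assert abs(sol.Na + sol.Np - cfg.mass * fluid.g) <= 1e-12


class TestMonotonicity:
    def test_anterior_load_nondecreasing_in_speed(self, fluid, saturating_model, medium_symmetric):
        """With a monotone wave kernel the resistance torque can only add
        anterior load as speed grows (checked across the convergent
        speed range of two representative configurations)."""
        long_sym = default_configuration("long", "P_tigrina", "symmetric")
        for cfg, u_max in ((medium_symmetric, 0.8), (long_sym, 1.5)):
            nas = []
            for u in np.linspace(0.0, u_max, 40):
                sol = solve_support_forces(cfg, float(u), fluid, saturating_model)
                assert sol.converged
                nas.append(sol.Na)
            assert all(b >= a - 1e-15 for a, b in zip(nas, nas[1:]))

    def test_resistance_presses_forelegs_down(self, fluid, model, medium_symmetric):
        static = solve_support_forces(medium_symmetric, 0.0, fluid, model)
        moving = solve_support_forces(medium_symmetric, 0.5, fluid, model)
        assert moving.Na > static.Na


class TestFloatability:
    def test_near_massless_slider_floats(self, fluid, model):
        legs_a = SupportLegSet(lengths=(2e-3, 2e-3), diameters=(2e-4, 2e-4), role=Role.ANTERIOR)
        legs_p = SupportLegSet(lengths=(0.02, 0.02), diameters=(2e-4, 2e-4), role=Role.POSTERIOR)
        cfg = SliderConfiguration(
            mass=1e-9, anterior=legs_a, posterior=legs_p, a=5e-3, b=5e-3, h=4e-3, gait=Gait.SYMMETRIC
        )
        sol = check_floatability(cfg, 0.0, fluid, model)
        assert not sol.breaks
        assert sol.margin == pytest.approx(sol.critical_force, rel=1e-4)

    def test_heaviest_short_foreleg_breaks_at_rest(self, fluid, model):
        cfg = default_configuration("short", "G_gigas_male", "symmetric")
        sol = check_floatability(cfg, 0.0, fluid, model)
        assert sol.breaks and sol.margin < 0

    def test_same_mass_long_foreleg_floats_at_rest(self, fluid, model):
        cfg = default_configuration("long", "G_gigas_male", "symmetric")
        sol = check_floatability(cfg, 0.0, fluid, model)
        assert not sol.breaks

    def test_same_mass_asymmetric_floats_at_rest(self, fluid, model):
        cfg = default_configuration("short", "G_gigas_male", "asymmetric")
        sol = check_floatability(cfg, 0.0, fluid, model)
        assert not sol.breaks

    def test_runaway_feedback_flagged_infeasible_and_breaking(self, fluid, model):
        # a short-foreleg symmetric slider at speed: wave feedback on the
        # tiny anterior contact has no fixed point
        cfg = default_configuration("short", "G_latiabdominis", "symmetric")
        sol = solve_support_forces(cfg, 1.0, fluid, model)
        assert sol.infeasible and not sol.converged
        assert sol.breaks
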