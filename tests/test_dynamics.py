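"""Sliding trajectories: limits, integrator cross-check, gait comparison."""

import numpy as np
import pytest

from striderslide import (
    DomainError,
    StopCriteria,
    critical_wave_speed,
    deceleration_at,
    default_configuration,
    default_gait_pair,
    gait_deceleration_gap,
    simulate_slide,
    solve_support_forces,
)


class TestDecelerationAt:
    def test_zero_at_rest(self, fluid, model, medium_symmetric):
        assert deceleration_at(medium_symmetric, 0.0, fluid, model) == 0.0

    def test_matches_resistance_over_mass(self, fluid, model, medium_symmetric):
        sol = solve_support_forces(medium_symmetric, 0.5, fluid, model)
        dec = deceleration_at(medium_symmetric, 0.5, fluid, model)
        assert dec == pytest.approx(sol.total_resistance / medium_symmetric.mass, rel=1e-9)

    @pytest.mark.parametrize("gait,speed", [("symmetric", 0.2), ("asymmetric", 0.2), ("asymmetric", 0.5)])
    def test_heavier_body_decelerates_less(self, fluid, model, gait, speed):
        """At equal speed a heavier slider of the same class loses speed
        more slowly (inequality only).  Checked where the resistance is
        dominated by skin friction — i.e. nearly load-independent; the
        load-quadratic wave drag on a short anterior support can invert
        the trend for fast symmetric sliding."""
        from striderslide import build_configuration

        light = build_configuration("intermediate", "A_paludum", gait, mass_kg=40e-6)
        heavy = build_configuration("intermediate", "A_paludum", gait, mass_kg=70e-6)
        assert deceleration_at(heavy, speed, fluid, model) < deceleration_at(light, speed, fluid, model)


class TestSimulateSlide:
    def test_zero_initial_speed_stops_immediately(self, fluid, model, medium_symmetric):
        traj = simulate_slide(medium_symmetric, 0.0, fluid, model)
        assert traj.termination == "stopped"
        assert traj.distance == 0.0
        assert traj.duration == 0.0

    def test_free_slide_preserves_velocity_exactly(self, fluid, model, medium_symmetric):
        stop = StopCriteria(U_stop=0.01, t_max=0.5)
        traj = simulate_slide(
            medium_symmetric, 0.4, fluid, model, dt=1e-3, stop=stop, include_resistance=False
        )
        assert traj.termination == "time_limit"
        assert all(v == 0.4 for v in traj.velocities)
        assert traj.distance == pytest.approx(0.4 * traj.duration, rel=1e-12)

    def test_invalid_step_rejected(self, fluid, model, medium_symmetric):
        with pytest.raises(DomainError):
            simulate_slide(medium_symmetric, 0.3, fluid, model, dt=0.0)

    def test_velocity_nonincreasing_position_nondecreasing(self, fluid, model, medium_symmetric):
        traj = simulate_slide(medium_symmetric, 0.5, fluid, model, dt=1e-3)
        v = traj.velocities
        x = traj.positions
        assert all(b <= a + 1e-15 for a, b in zip(v, v[1:]))
        assert all(b >= a - 1e-15 for a, b in zip(x, x[1:]))

    def test_recorded_deceleration_matches_statics(self, fluid, model, medium_symmetric):
        traj = simulate_slide(medium_symmetric, 0.5, fluid, model, dt=1e-3)
        m = medium_symmetric.mass
        for dec, sol in zip(traj.decelerations, traj.statics_per_step):
            if sol is not None:
                assert dec * m == pytest.approx(sol.total_resistance, rel=1e-9)

    def test_rk4_agrees_with_fine_euler_oracle(self, fluid, model, medium_symmetric):
        """Coarse RK4 and a 100x-finer explicit-Euler reference agree on
        the sliding distance to 0.1%."""
        stop = StopCriteria(U_stop=0.01, t_max=0.4)
        rk4 = simulate_slide(medium_symmetric, 0.6, fluid, model, dt=1e-4, stop=stop)
        euler = simulate_slide(medium_symmetric, 0.6, fluid, model, dt=1e-6, stop=stop, method="euler")
        assert abs(rk4.distance - euler.distance) / euler.distance <= 1e-3

    def test_distance_monotone_in_launch_speed(self, fluid, model, medium_symmetric):
        stop = StopCriteria(U_stop=0.01, t_max=1.0)
        distances = [
            simulate_slide(medium_symmetric, u0, fluid, model, dt=1e-3, stop=stop).distance
            for u0 in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(b > a for a, b in zip(distances, distances[1:]))

    def test_energy_bookkeeping(self, fluid, model, medium_symmetric):
        """Kinetic-energy loss equals the trapezoid work of the recorded
        resistance over the recorded path."""
        traj = simulate_slide(medium_symmetric, 0.6, fluid, model, dt=1e-4, stop=StopCriteria(t_max=0.3))
        m = medium_symmetric.mass
        ke_loss = 0.5 * m * (traj.velocities[0] ** 2 - traj.velocities[-1] ** 2)
        forces = [dec * m for dec in traj.decelerations]
        work = sum(
            0.5 * (forces[i] + forces[i + 1]) * (traj.positions[i + 1] - traj.positions[i])
            for i in range(len(forces) - 1)
        )
        assert work == pytest.approx(ke_loss, rel=1e-3)

    def test_finite_difference_deceleration_round_trip(self, fluid, model, medium_symmetric):
        """Deceleration recovered from the velocity series by central
        differences matches the model's R/m at matching speeds to 1%."""
        traj = simulate_slide(medium_symmetric, 0.6, fluid, model, dt=1e-4, stop=StopCriteria(t_max=0.2))
        t = np.array(traj.times)
        v = np.array(traj.velocities)
        for k in range(50, len(t) - 50, 400):
            dec_fd = (v[k - 1] - v[k + 1]) / (t[k + 1] - t[k - 1])
            dec_model = deceleration_at(medium_symmetric, float(v[k]), fluid, model)
            assert dec_fd == pytest.approx(dec_model, rel=1e-2)

    def test_meniscus_break_terminates_slide(self, fluid, model):
        """A heavy short-foreleg symmetric slider pierces the surface as
        soon as it moves fast enough for the wave feedback to load its
        forelegs past the capillary maximum — here already at launch."""
        cfg = default_configuration("short", "G_gigas_male", "symmetric")
        traj = simulate_slide(cfg, 0.5, fluid, model, dt=1e-3)
        assert traj.termination == "meniscus_break"


class TestGaitGap:
    def test_mass_mismatch_rejected(self, fluid, model):
        sym, _ = default_gait_pair()
        heavy_asym = default_configuration("intermediate", "P_tigrina", "asymmetric")
        with pytest.raises(DomainError):
            gait_deceleration_gap(sym, heavy_asym, [0.1], fluid, model)

    def test_zero_gap_at_rest(self, fluid, model):
        sym, asym = default_gait_pair()
        (_, gap0), = gait_deceleration_gap(sym, asym, [0.0], fluid, model)
        assert gap0 == 0.0

    def test_gap_nonnegative_and_positive_above_threshold(self, fluid, model):
        sym, asym = default_gait_pair()
        c = critical_wave_speed(fluid)
        grid = np.linspace(0.0, 1.5, 31)
        gaps = dict(gait_deceleration_gap(sym, asym, grid, fluid, model))
        for u, g in gaps.items():
            assert g >= -1e-12
            if u > 1.05 * c:
                assert g > 0.0

    def test_gap_peaks_at_moderate_speed(self, fluid, model):
        """The symmetric-asymmetric deceleration gap is largest shortly
        above the wave-making threshold, not at the fastest slides."""
        sym, asym = default_gait_pair()
        grid = np.linspace(0.0, 1.5, 61)
        gaps = np.array([g for _, g in gait_deceleration_gap(sym, asym, grid, fluid, model)])
        u_star = grid[int(np.argmax(gaps))]
        assert 0.3 <= u_star <= 0.7
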