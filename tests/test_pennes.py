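"""Pennes bioheat solver: baselines, transients, pulses, energy balance."""

import numpy as np
import pytest

from skintherm import (
    PulseSchedule,
    ThermalBoundary,
    ThermalSettings,
    build_stack,
    make_grid,
    pulse_signal,
    pulsed_plateau_rise,
    solve_baseline,
    solve_steady_rise,
    solve_transient,
    steady_max_rise,
)

from conftest import homogeneous_stack, small_thermal_problem


class TestPulseSignal:
    @pytest.mark.parametrize(
        "duty, f, t, expect",
        [
            (0.5, 1.0, 0.25, 1.0),  # ON for the first half second
            (0.5, 1.0, 0.75, 0.0),
            (1.0, 1.0, 123.4, 1.0),
            (0.2, 10.0, 0.019, 1.0),
            (0.2, 10.0, 0.021, 0.0),
        ],
    )
    def test_square_wave(self, duty, f, t, expect):
        s = PulseSchedule(duty_cycle=duty, frequency=f)
        assert pulse_signal(s, t) == expect

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pulse_signal(PulseSchedule(), -1.0)


class TestBaseline:
    def test_perfusion_fixed_point(self):
        """h = 0, Q_met = 0: the only steady state is T = T_b everywhere."""
        stack = build_stack(
            [dict(name="a", thickness_mm=1.0, mu_a_per_cm=1.0, perfused=False),
             dict(name="b", thickness_mm=1.0, mu_a_per_cm=1.0, perfused=True)],
            blood=dict(metabolic_heat_w_m3=0.0),
        )
        grid = make_grid(stack, dr=1e-3, dz=1e-4, r_max=10e-3)
        T = solve_baseline(stack, grid, ThermalBoundary(h=0.0))
        assert np.allclose(T, stack.blood.T_b, atol=1e-8)

    def test_uniform_metabolic_offset(self):
        """Zero-gradient balance: T = T_b + Q_met / (rho_b c_pb omega_b)."""
        stack = homogeneous_stack(perfused=True)
        grid = make_grid(stack, dr=1e-3, dz=2e-4, r_max=10e-3)
        T = solve_baseline(stack, grid, ThermalBoundary(h=0.0))
        b = stack.blood
        expect = b.T_b + b.q_met / (b.rho_b * b.c_pb * b.omega_b)
        assert np.allclose(T, expect, atol=1e-6)

    def test_surface_between_ambient_and_arterial(self, thz130):
        grid = make_grid(thz130.stack, dr=2e-3, dz=5e-5, r_max=60e-3)
        bnd = ThermalBoundary(h=10.0, T_ambient=296.15)
        T = solve_baseline(thz130.stack, grid, bnd)
        b = thz130.stack.blood
        # metabolic heat can push the interior slightly above T_b, but the
        # cooled surface must sit strictly between ambient and the interior
        assert bnd.T_ambient < T[0, :].min()
        assert T[0, :].max() < T.max() <= b.T_b + b.q_met / (
            b.rho_b * b.c_pb * b.omega_b
        ) + 1e-6

    def test_unbounded_steady_state_rejected(self):
        stack = homogeneous_stack(perfused=False)  # q_met > 0, no sink
        grid = make_grid(stack, dr=1e-3, dz=2e-4, r_max=10e-3)
        with pytest.raises(ValueError, match="unbounded"):
            solve_baseline(stack, grid, ThermalBoundary(h=0.0))


class TestTransient:
    def test_zero_source_stays_at_baseline(self):
        stack, grid, _ = small_thermal_problem()
        res = solve_transient(stack, grid, ThermalBoundary(),
                              np.zeros((grid.nz, grid.nr)),
                              settings=ThermalSettings(dt=1.0, t_end=10.0))
        assert np.all(np.abs(res.T_max_rise) < 1e-9)

    def test_rise_monotone_and_flattening_for_continuous_source(self):
        stack, grid, q = small_thermal_problem()
        res = solve_transient(stack, grid, ThermalBoundary(), q,
                              settings=ThermalSettings(dt=2.0, t_end=240.0))
        r = res.T_max_rise
        assert np.all(np.diff(r) >= -1e-12)
        # asymptotic flattening: late increments smaller than early ones
        assert (r[-1] - r[-2]) < 0.1 * (r[1] - r[0])

    def test_transient_approaches_steady_solution(self):
        stack, grid, q = small_thermal_problem()
        steady = float(np.max(solve_steady_rise(stack, grid, ThermalBoundary(), q)))
        res = solve_transient(stack, grid, ThermalBoundary(), q,
                              settings=ThermalSettings(dt=5.0, t_end=3000.0))
        assert res.T_max_rise[-1] == pytest.approx(steady, rel=0.01)

    def test_steady_rise_linearity_in_source(self):
        stack, grid, q = small_thermal_problem()
        r1 = solve_steady_rise(stack, grid, ThermalBoundary(), q)
        r2 = solve_steady_rise(stack, grid, ThermalBoundary(), 2.0 * q)
        assert np.allclose(r2, 2.0 * r1, rtol=1e-10)

    def test_crank_nicolson_matches_backward_euler_plateau(self):
        stack, grid, q = small_thermal_problem()
        be = solve_transient(stack, grid, ThermalBoundary(), q,
                             settings=ThermalSettings(dt=2.0, t_end=400.0))
        cn = solve_transient(stack, grid, ThermalBoundary(), q,
                             settings=ThermalSettings(dt=2.0, t_end=400.0,
                                                      scheme="crank_nicolson"))
        assert cn.T_max_rise[-1] == pytest.approx(be.T_max_rise[-1], rel=0.01)

    def test_time_step_refinement_stability(self):
        stack, grid, q = small_thermal_problem()
        a = solve_transient(stack, grid, ThermalBoundary(), q,
                            settings=ThermalSettings(dt=4.0, t_end=400.0))
        b = solve_transient(stack, grid, ThermalBoundary(), q,
                            settings=ThermalSettings(dt=2.0, t_end=400.0))
        assert b.T_max_rise[-1] == pytest.approx(a.T_max_rise[-1], rel=0.005)

    def test_snapshots_recorded(self):
        stack, grid, q = small_thermal_problem()
        res = solve_transient(stack, grid, ThermalBoundary(), q,
                              settings=ThermalSettings(dt=1.0, t_end=5.0,
                                                       snapshot_times=(3.0,)))
        assert 3.0 in res.snapshots
        assert res.snapshots[3.0].shape == (grid.nz, grid.nr)

    def test_unresolved_pulse_dt_rejected(self):
        stack, grid, q = small_thermal_problem()
        with pytest.raises(ValueError, match="resolve"):
            solve_transient(stack, grid, ThermalBoundary(), q,
                            schedule=PulseSchedule(duty_cycle=0.5, frequency=1.0),
                            settings=ThermalSettings(dt=0.2, t_end=10.0))


class TestSteadyMaxRise:
    def test_zero_source_plateau_is_zero(self):
        stack, grid, _ = small_thermal_problem()
        res = solve_transient(stack, grid, ThermalBoundary(),
                              np.zeros((grid.nz, grid.nr)),
                              settings=ThermalSettings(dt=1.0, t_end=20.0))
        assert steady_max_rise(res) == pytest.approx(0.0, abs=1e-9)

    def test_unconverged_run_raises(self):
        stack, grid, q = small_thermal_problem()
        res = solve_transient(stack, grid, ThermalBoundary(), q,
                              settings=ThermalSettings(dt=1.0, t_end=10.0))
        with pytest.raises(ValueError, match="t_end"):
            steady_max_rise(res, tol=1e-6)


class TestEnergyBalance:
    def test_steady_source_power_equals_sinks(self):
        """At the plateau, deposited power = extra convective + perfusion
        losses relative to baseline (discrete energy balance)."""
        stack, grid, q = small_thermal_problem()
        bnd = ThermalBoundary()
        dT = solve_steady_rise(stack, grid, bnd, q)
        vol = grid.cell_volumes
        source = float((q * vol).sum())
        b = stack.blood
        perf = b.rho_b * b.c_pb * b.omega_b * float((dT * vol).sum())
        ring = grid.ring_areas
        U = 1.0 / (1.0 / bnd.h + 0.5 * grid.dz[0] / stack.layers[0].thermal.k)
        conv = float((U * ring * dT[0, :]).sum())
        assert perf + conv == pytest.approx(source, rel=0.005)


class TestPulsedPlateau:
    def test_duty_cycle_scales_plateau(self):
        stack, grid, q = small_thermal_problem()
        cont = float(np.max(solve_steady_rise(stack, grid, ThermalBoundary(), q)))
        half = pulsed_plateau_rise(stack, grid, ThermalBoundary(), q,
                                   PulseSchedule(duty_cycle=0.5, frequency=2.0))
        assert half == pytest.approx(0.5 * cont, rel=0.05)

    def test_continuous_schedule_returns_steady(self):
        stack, grid, q = small_thermal_problem()
        cont = float(np.max(solve_steady_rise(stack, grid, ThermalBoundary(), q)))
        same = pulsed_plateau_rise(stack, grid, ThermalBoundary(), q,
                                   PulseSchedule())
        assert same == pytest.approx(cont, rel=1e-12)
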