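"""Wall kinematics: front transit, occlusion field, pyloric schedule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from gastroflow.motility import (
    MotilityEvaluator,
    PyloricSchedule,
    WaveParams,
    contraction_width,
    front_distance,
    occlusion_field,
    open_during_relaxation,
    open_during_tac,
    pylorus_open_fraction,
    relaxation_window,
    tac_window,
    wall_state,
    wave_front_position,
)


def uniform_wave(origin=100.0):
    """Constant-speed wave (no TAC acceleration) for kinematics checks."""
    return WaveParams(
        origin_d=origin,
        velocity_profile=((0.0, 1.0), (origin, 1.0)),
        epsilon_profile=((0.0, 0.9), (origin, 0.3)),
    )


class TestFrontKinematics:
    def test_uniform_speed_travel(self):
        # 2.5 mm/s for 20 s from 100 mm -> front at 50 mm
        assert front_distance(20.0, uniform_wave()) == pytest.approx(50.0, rel=1e-6)

    def test_front_at_origin_at_age_zero(self):
        assert front_distance(0.0, WaveParams()) == pytest.approx(110.0)

    def test_piecewise_speed_against_ode_oracle(self):
        # speed doubles inside the TAC zone: the last 30 mm take 30/(2*2.5) s
        wave = WaveParams(velocity_profile=((0.0, 2.0), (29.999, 2.0), (30.0, 1.0)))
        t_zone = front_distance(0.0, wave)  # just touch the API
        kin_transit = None
        # closed form: (110-30)/2.5 + 30/5
        t_total_ref = (110.0 - 30.0) / 2.5 + 30.0 / 5.0
        # independent oracle: integrate ds/dt = -V(s)
        sol = solve_ivp(
            lambda t, s: -wave.speed(s), (0.0, t_total_ref * 1.1), [110.0],
            dense_output=True, rtol=1e-9, atol=1e-9,
        )
        d_num = float(sol.sol(t_total_ref)[0])
        assert abs(d_num) < 0.1  # oracle: front reaches the pylorus then
        assert front_distance(t_total_ref, wave) == pytest.approx(0.0, abs=0.1)

    def test_concurrent_fronts(self):
        fronts = wave_front_position(12.0, WaveParams())
        assert len(fronts) >= 2  # transit time exceeds one period


class TestContractionWidth:
    @pytest.mark.parametrize("d,expected", [(40.0, 18.0), (0.0, 54.0), (15.0, 36.0)])
    def test_printed_profile(self, d, expected):
        assert contraction_width(d, WaveParams()) == pytest.approx(expected)


class TestOcclusionField:
    def test_zero_far_from_fronts(self):
        wave = uniform_wave()
        from gastroflow.motility import _FrontKinematics

        kin = _FrontKinematics(wave)
        fronts = kin.front_distance(kin.active_ages(0.0))
        probe = 85.0  # clear of every front by more than the local width
        assert all(abs(probe - f) > wave.width(f) for f in np.atleast_1d(fronts))
        assert occlusion_field(probe, 0.0, wave)[0] == 0.0

    def test_front_centre_carries_front_depth(self):
        wave = uniform_wave()
        # wave initiated per phase convention; front of age 20 s is at d=50
        kin_front = 50.0
        t = 20.0 + __import__("gastroflow.motility", fromlist=["_FrontKinematics"])._FrontKinematics(wave).t_init
        eps = occlusion_field(kin_front, t, wave)
        assert eps[0] == pytest.approx(float(wave.epsilon(kin_front)), rel=1e-3)

    def test_occlusion_bounded_below_one(self, geom):
        wave = WaveParams()
        s = np.linspace(7.0, geom.s_max, 300)
        for t in np.linspace(0, 40, 17):
            eps = occlusion_field(s, float(t), wave)
            assert (eps <= wave.eps_max).all()


class TestPyloricSchedule:
    def test_control_open_window(self):
        sched = PyloricSchedule.control()
        # closure interval [0.6, 1.2667) mod 1, ramps of 0.1 following each
        # endpoint: fully open on (0.3667, 0.6), fully closed on (0.7, 0.2667)
        assert pylorus_open_fraction(0.5 * 20, sched) == 1.0
        assert pylorus_open_fraction(0.45 * 20, sched) == 1.0
        assert pylorus_open_fraction(0.75 * 20, sched) == 0.0
        assert pylorus_open_fraction(0.1 * 20, sched) == 0.0
        # mid-ramp: begins to close at 0.6, begins to open at 0.2667
        assert 0.0 < pylorus_open_fraction(0.65 * 20, sched) < 1.0
        assert 0.0 < pylorus_open_fraction(0.32 * 20, sched) < 1.0

    def test_always_open_and_always_closed(self):
        t = np.linspace(0, 40, 201)
        assert (pylorus_open_fraction(t, PyloricSchedule(T_C=0.0)) == 1.0).all()
        assert (pylorus_open_fraction(t, PyloricSchedule(T_C=20.0)) == 0.0).all()

    @given(
        tc=st.floats(0.05, 0.95),
        td=st.floats(0.0, 1.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_open_fraction_time_average(self, tc, td):
        # straddling trapezoidal ramps make the average exactly 1 - T_C/T
        sched = PyloricSchedule(T_C=tc * 20, T_D=td * 20)
        t = np.linspace(0, 20, 200_001)
        avg = np.trapezoid(pylorus_open_fraction(t, sched), t) / 20.0
        assert avg == pytest.approx(1.0 - tc, abs=2e-4)

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            PyloricSchedule(T_C=-1.0)
        with pytest.raises(ValueError):
            PyloricSchedule(T_C=5.0, T_D=25.0)


class TestWallState:
    def test_velocity_matches_finite_difference(self, geom):
        wave, sched = WaveParams(), PyloricSchedule.control()
        s = np.linspace(geom.s_min, geom.s_max, 200)
        t0 = 13.4  # mid-TAC, walls moving, clear of schedule-ramp kinks
        ws = wall_state(t0, geom, wave, sched, s)
        errs = []
        for dt in (0.08, 0.04):
            r_p = wall_state(t0 + dt, geom, wave, sched, s).r
            r_m = wall_state(t0 - dt, geom, wave, sched, s).r
            errs.append(np.mean(np.abs((r_p - r_m) / (2 * dt) - ws.drdt)))
        # ~quadratic convergence away from profile kinks; strictly decreasing
        assert errs[1] <= errs[0] / 2.0
        assert errs[1] <= 0.01 * np.abs(ws.drdt).max()

    def test_static_wave_zero_velocity(self, geom):
        sched = PyloricSchedule(T_C=0.0)  # no pyloric ramps either
        ws = wall_state(5.0, geom, None, sched)
        assert np.abs(ws.drdt).max() == 0.0

    def test_periodicity_after_spinup(self, geom):
        wave, sched = WaveParams(), PyloricSchedule.control()
        s = np.linspace(geom.s_min, geom.s_max, 150)
        a = wall_state(80.0, geom, wave, sched, s)
        b = wall_state(100.0, geom, wave, sched, s)
        np.testing.assert_allclose(a.r, b.r, atol=1e-9)
        np.testing.assert_allclose(a.drdt, b.drdt, atol=1e-6)

    def test_pylorus_closes_fully(self, geom):
        sched = PyloricSchedule.control()
        ws = wall_state(0.7 * 20, geom, WaveParams(), sched, np.array([0.0]))
        assert ws.pylorus_open_fraction == 0.0
        assert ws.r[0] == pytest.approx(0.0, abs=1e-9)

    def test_control_tac_and_closure_coincide(self):
        wave, sched = WaveParams(), PyloricSchedule.control()
        tac_start, _ = tac_window(wave)
        closure_start = sched.tac_onset_frac * sched.T + sched.T_D
        assert tac_start == pytest.approx(closure_start)
        # front is entering the TAC zone right then
        fronts = wave_front_position(tac_start, wave)
        assert np.min(np.abs(fronts - 30.0)) < 0.5


class TestCoordinationPredicates:
    @pytest.mark.parametrize(
        "tc_frac,td_frac,during_tac,during_relax",
        [
            (2 / 3, 0.0, False, False),  # control: closed through TAC and relaxation
            (2 / 3, 1 / 8, True, False),  # delayed closure: open during TAC
            (2 / 3, 3 / 8, True, True),  # open only late: relaxation exposure
            (0.0, 0.0, True, True),  # pylorus unable to close
        ],
    )
    def test_predicates(self, tc_frac, td_frac, during_tac, during_relax):
        wave = WaveParams()
        sched = PyloricSchedule(T_C=tc_frac * 20, T_D=td_frac * 20)
        assert open_during_tac(sched, wave) is during_tac
        assert open_during_relaxation(sched, wave) is during_relax

    def test_windows_are_ordered(self):
        wave = WaveParams()
        t0, t1 = tac_window(wave)
        r0, r1 = relaxation_window(wave)
        assert t0 < t1 == r0 < r1
        # TAC spans roughly [0.6, 0.8] of the cycle by construction
        assert t0 / 20 == pytest.approx(0.6)
        assert t1 / 20 == pytest.approx(0.8, abs=0.02)
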