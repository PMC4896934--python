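"""Baroreflex afferent filter, efferent activities, effector responses."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioresp import baroreflex as B


class TestAfferentFilter:
    def test_dc_equilibrium(self):
        assert B.afferent_filter_derivative(90.0, 0.0, 90.0, 2.076, 6.37) == 0.0

    def test_step_response_follows_first_order_closed_form(self):
        tau_p, tau_z = 2.076, 6.37
        paa, p0 = 100.0, 90.0
        dt, p = 1e-4, p0
        for _ in range(int(2.0 / dt)):  # 2 s after the step (dPaa/dt = 0)
            p += dt * B.afferent_filter_derivative(paa, 0.0, p, tau_p, tau_z)
        expected = paa + (p0 - paa) * math.exp(-2.0 / tau_p)
        assert p == pytest.approx(expected, rel=1e-4)

    def test_unit_dc_gain_with_lead(self):
        # for constant dPaa/dt the filter output tracks Paa + tau_z*dPaa/dt
        d = B.afferent_filter_derivative(90.0, 2.0, 90.0 + 6.37 * 2.0,
                                         2.076, 6.37)
        assert d == pytest.approx(0.0, abs=1e-12)


class TestSetPoint:
    def test_resting_and_reset_values(self, healthy, hf):
        assert B.set_point_pressure(0.0, healthy.Paa_set0, healthy.A) == 90.0
        assert B.set_point_pressure(73.0, healthy.Paa_set0, healthy.A) == \
            pytest.approx(107.666, abs=1e-3)
        assert B.set_point_pressure(73.0, hf.Paa_set0, hf.A) == \
            pytest.approx(118.674, abs=1e-3)


class TestAfferentFiring:
    def test_central_point_and_saturations(self, healthy):
        fmin, fmax, ka = healthy.Fas_min, healthy.Fas_max, healthy.ka
        assert B.afferent_firing(90.0, 90.0, ka, fmin, fmax) == \
            pytest.approx(0.5 * (fmin + fmax))
        assert B.afferent_firing(-1e3, 90.0, ka, fmin, fmax) == \
            pytest.approx(fmin, abs=1e-6)
        assert B.afferent_firing(1e3, 90.0, ka, fmin, fmax) == \
            pytest.approx(fmax, abs=1e-6)

    def test_central_slope(self, healthy):
        fmin, fmax, ka = healthy.Fas_min, healthy.Fas_max, healthy.ka
        h = 1e-6
        slope = (B.afferent_firing(90 + h, 90, ka, fmin, fmax)
                 - B.afferent_firing(90 - h, 90, ka, fmin, fmax)) / (2 * h)
        assert slope == pytest.approx((fmax - fmin) / (4 * ka), rel=1e-6)

    @given(p=st.floats(0, 200), dp=st.floats(0.01, 30))
    def test_strictly_increasing_in_pressure(self, p, dp):
        a1 = B.afferent_firing(p, 90.0, 11.758, 2.52, 47.78)
        a2 = B.afferent_firing(p + dp, 90.0, 11.758, 2.52, 47.78)
        assert a2 > a1

    def test_resetting_is_a_horizontal_translation(self, healthy):
        # Fas depends on P - Paa_set only: curves at different workloads are
        # shifted copies of each other
        for p in (60.0, 90.0, 130.0):
            at_rest = B.afferent_firing(p, 90.0, healthy.ka,
                                        healthy.Fas_min, healthy.Fas_max)
            shift = healthy.A * 73.0
            at_73 = B.afferent_firing(p + shift, 90.0 + shift, healthy.ka,
                                      healthy.Fas_min, healthy.Fas_max)
            assert at_73 == pytest.approx(at_rest, rel=1e-12)


class TestEfferentActivities:
    def test_sympathetic_limits(self, healthy):
        args = (healthy.Fes0, healthy.Fes_inf, healthy.kes)
        assert B.sympathetic_activity(1e6, 0.0, *args, 0.12) == \
            pytest.approx(2.10, abs=1e-9)
        assert B.sympathetic_activity(0.0, 0.0, *args, 0.12) == \
            pytest.approx(16.11, abs=1e-9)

    def test_exercise_offset(self, healthy):
        args = (healthy.Fes0, healthy.Fes_inf, healthy.kes)
        base = B.sympathetic_activity(20.0, 0.0, *args, healthy.B)
        assert B.sympathetic_activity(20.0, 73.0, *args, healthy.B) == \
            pytest.approx(base + 0.12 * 73.0)

    def test_vagal_central_value_at_rest(self, healthy):
        fas0 = B.central_fas(healthy)
        fev = B.vagal_activity(fas0, 0.0, healthy.Fev0, healthy.Fev_inf0,
                               healthy.kev, fas0, healthy.C, healthy.D)
        assert fev == pytest.approx(0.5 * (3.2 + 6.3), rel=1e-12)

    def test_complete_withdrawal_at_high_workload(self, healthy):
        fas0 = B.central_fas(healthy)
        for fas in (0.0, fas0, 3 * fas0):
            fev = B.vagal_activity(fas, 150.0, healthy.Fev0,
                                   healthy.Fev_inf0, healthy.kev, fas0,
                                   healthy.C, healthy.D)
            assert fev == 0.0

    @given(wl=st.floats(0, 100), dwl=st.floats(0.1, 40),
           fas=st.floats(0, 60))
    def test_vagal_non_increasing_in_workload(self, wl, dwl, fas):
        a1 = B.vagal_activity(fas, wl, 3.2, 6.3, 7.06, 25.15, -0.041, -0.044)
        a2 = B.vagal_activity(fas, wl + dwl, 3.2, 6.3, 7.06, 25.15,
                              -0.041, -0.044)
        assert a2 <= a1 + 1e-12


class TestEffectorResponses:
    def test_static_responses_vanish_at_set_point(self, healthy):
        fes_set, fev_set = B.rest_set_activities(healthy)
        assert B.effector_static_sympathetic(fes_set, fes_set,
                                             healthy.Fes_inf, -0.09) == 0.0
        assert B.effector_static_vagal(fev_set, fev_set, 0.07) == 0.0

    def test_vagal_static_gain(self):
        assert B.effector_static_vagal(7.35, 6.35, 0.07) == \
            pytest.approx(0.07)

    def test_sympathetic_static_monotone_and_compressive(self, healthy):
        fes_set, _ = B.rest_set_activities(healthy)
        vals = [B.effector_static_sympathetic(f, fes_set, healthy.Fes_inf,
                                              1.0)
                for f in (3.0, 6.0, 12.0, 24.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        # log compression: equal multiplicative steps give shrinking gains
        assert vals[3] - vals[2] < vals[1] - vals[0] + 1.0

    def test_first_order_block_steady_state(self):
        # dΔ/dt = (sf - Δ)/T: integrate a held step, compare closed form
        sf, tau, dt = 0.5, 2.0, 1e-3
        delta = 0.0
        for _ in range(int(4.0 / dt)):
            delta += dt * B.effector_dynamics_derivative(sf, delta, tau)
        assert delta == pytest.approx(sf * (1 - math.exp(-2.0)), rel=1e-3)


class TestOpenLoop:
    def test_set_point_contract_at_rest(self, healthy, hf):
        # holding the filtered pressure at the rest set point leaves the
        # heart period exactly at its set-point value
        for prof in (healthy, hf):
            tc = B.steady_heart_period(prof, prof.Paa_set0, 0.0)
            assert tc == pytest.approx(60.0 / prof.HR_set, rel=1e-12)

    def test_hr_decreases_with_imposed_pressure(self, healthy):
        res = B.open_loop_response_curve(healthy, 0.0,
                                         np.arange(0.0, 201.0, 5.0))
        assert np.all(np.diff(res["hr"]) <= 1e-9)
        assert np.all(np.diff(res["fas"]) > 0)
        assert np.all(np.diff(res["fes"]) < 0)
        assert np.all(np.diff(res["fev"]) >= 0)

    def test_resetting_shifts_the_operating_point_upward(self, healthy):
        # the reflex family moves to higher HR with workload at the
        # respective operating points
        hrs = [B.operating_point_hr(healthy, wl) for wl in (0, 35, 61, 87)]
        assert all(b > a for a, b in zip(hrs, hrs[1:]))

    def test_single_channel_sweeps_match_blockade_experiments(self, healthy):
        # vagal-withdrawal channel alone: 58 -> ~84 bpm from rest to 73 W;
        # sympathetic channel alone: 58 -> ~65 bpm
        hv0 = B.operating_point_hr(healthy, 0.0, sympathetic=False)
        hv73 = B.operating_point_hr(healthy, 73.0, sympathetic=False)
        hs0 = B.operating_point_hr(healthy, 0.0, vagal=False)
        hs73 = B.operating_point_hr(healthy, 73.0, vagal=False)
        assert hv0 == pytest.approx(58.0, abs=0.1)
        assert hs0 == pytest.approx(58.0, abs=0.1)
        assert 80.0 < hv73 < 90.0
        assert 63.0 < hs73 < 68.0
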