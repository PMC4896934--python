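"""Chamber laws, valves, Starling resistor, muscle pump, network closure."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioresp import hemodynamics as H
from cardioresp import state as S


class TestChamberPressures:
    def test_atrial_pressure_examples(self):
        assert H.atrial_pressure(100.0, 25.0, 100.0, 0.0) == 0.0
        assert H.atrial_pressure(125.0, 25.0, 100.0, 0.0) == pytest.approx(1.0)
        assert H.atrial_pressure(125.0, 25.0, 100.0, -4.0) == pytest.approx(-3.0)

    @given(v=st.floats(0, 500), c=st.floats(1, 60), v0=st.floats(0, 200),
           pintr=st.floats(-10, 5))
    def test_atrial_pressure_linear_in_volume(self, v, c, v0, pintr):
        p1 = H.atrial_pressure(v, c, v0, pintr)
        p2 = H.atrial_pressure(v + 10.0, c, v0, pintr)
        assert p2 - p1 == pytest.approx(10.0 / c, rel=1e-9)

    def test_ventricular_pressure_peak_systole(self):
        # full activation: pure elastance law
        tc = 60.0 / 58.0
        t_peak = 0.5 * 0.3 * math.sqrt(tc)   # phi = 1
        p = H.ventricular_pressure(120.0, t_peak, tc, 2.5, 5.0,
                                   0.033, 0.034, 8.0, 0.0)
        assert p == pytest.approx(2.5 * (120.0 - 5.0), rel=1e-12)

    def test_ventricular_pressure_diastole_is_passive(self):
        tc = 1.0
        p = H.ventricular_pressure(100.0, 0.9 * tc, tc, 2.5, 5.0,
                                   0.033, 0.034, 8.0, 0.0)
        assert p == pytest.approx(0.033 * math.exp(3.4) + 8.0, rel=1e-12)
        assert p == pytest.approx(8.99, abs=0.01)

    def test_activation_endpoints_and_range(self):
        tc = 0.8
        t_sys = 0.3 * math.sqrt(tc)
        assert H.activation(0.0, tc) == 0.0
        assert H.activation(t_sys, tc) == 0.0
        assert H.activation(0.5 * t_sys, tc) == pytest.approx(1.0)
        for f in np.linspace(0, 1, 21):
            assert 0.0 <= H.activation(f * tc, tc) <= 1.0


class TestValvesAndStarling:
    def test_valve_flow_examples(self):
        assert H.valve_flow(10.0, 5.0, 0.02) == pytest.approx(250.0)
        assert H.valve_flow(5.0, 10.0, 0.02) == 0.0
        assert H.valve_flow(5.0, 5.0, 0.02) == 0.0

    @given(pu=st.floats(-20, 200), pd_=st.floats(-20, 200),
           r=st.floats(0.001, 20))
    def test_valve_flow_never_negative(self, pu, pd_, r):
        assert H.valve_flow(pu, pd_, r) >= 0.0

    def test_starling_regimes(self):
        r = 0.01
        assert H.starling_resistor_flow(8, 4, 0, r) == pytest.approx(400.0)
        # waterfall: downstream pressure irrelevant
        assert H.starling_resistor_flow(8, 2, 4, r) == pytest.approx(400.0)
        assert H.starling_resistor_flow(8, -5, 4, r) == pytest.approx(400.0)
        assert H.starling_resistor_flow(3, 2, 5, r) == 0.0

    @given(pin=st.floats(-10, 60), pout=st.floats(-10, 60),
           pe1=st.floats(-10, 60), delta=st.floats(0, 30))
    @settings(max_examples=200)
    def test_starling_flow_non_increasing_in_external_pressure(
            self, pin, pout, pe1, delta):
        r = 0.01
        q1 = H.starling_resistor_flow(pin, pout, pe1, r)
        q2 = H.starling_resistor_flow(pin, pout, pe1 + delta, r)
        assert q2 <= q1 + 1e-12


class TestMusclePump:
    def test_rest_is_silent(self):
        assert H.muscle_pump_pressure(0.37, 0.0, 0.562) == (0.0, 0.0)

    def test_peak_pressure_at_73_watts(self):
        p_ll, _ = H.muscle_pump_pressure(0.25, 73.0, 0.562)  # sin = 1
        assert p_ll == pytest.approx(2 * 0.562 * 73.0, rel=1e-12)

    @given(t=st.floats(0, 10))
    def test_antiphase_sum_constant(self, t):
        p_ll, p_rl = H.muscle_pump_pressure(t, 73.0, 0.562)
        assert p_ll >= 0 and p_rl >= 0
        assert p_ll + p_rl == pytest.approx(2 * 0.562 * 73.0, abs=1e-9)


class TestNetworkClosure:
    def _derivs(self, healthy, x):
        p = healthy.to_array()
        dx = np.zeros(S.NX)
        eff = dict(elmax=2.5, ermax=1.1, tc=60 / 58,
                   r_uba=3.52, r_kida=3.62, r_spa=2.69, r_lla=12.6,
                   r_rla=12.6, r_ubv=0.23, r_kidv=0.3, r_spv=0.18,
                   r_llv=0.6, r_rlv=0.6, vub0=650.0, vkid0=150.0,
                   vsp0=1300.0, vll0=175.0, vrl0=175.0,
                   pintr=0.0, pim_ll=0.0, pim_rl=0.0)
        H.circulation_derivatives(x, dx, p, *eff.values())
        return dx

    def test_blood_volume_conserved_by_construction(self, healthy):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = np.zeros(S.NX)
            x[:16] = rng.uniform(20, 2000, 16)
            x[S.QAO], x[S.QPA] = rng.uniform(-100, 300, 2)
            x[S.TCPH] = rng.uniform(0, 1.0)
            dx = self._derivs(healthy, x)
            assert abs(dx[:16].sum()) < 1e-9 * max(1.0, np.abs(dx[:16]).max())

    def test_uniform_pressure_equilibrium(self, healthy):
        # every compartment at 10 mmHg transmural, diastolic heart at the
        # passive volume that also gives 10 mmHg -> no flow anywhere
        p0 = 10.0
        p = healthy.to_array()
        x = np.zeros(S.NX)
        x[S.VLA] = 25.0 * p0
        x[S.VRA] = 25.0 * p0
        x[S.VLV] = math.log((p0 - 8.0) / 0.033) / 0.034
        x[S.VRV] = math.log((p0 - 5.0) / 0.05) / 0.04
        x[S.VAA] = 0.8 * p0
        x[S.VABD] = 0.6 * p0
        x[S.VUB] = 650 + 8 * p0
        x[S.VKID] = 150 + 15 * p0
        x[S.VSP] = 1300 + 55 * p0
        x[S.VLL] = 175 + 9.5 * p0
        x[S.VRL] = 175 + 9.5 * p0
        x[S.VSUP] = 15 * p0
        x[S.VINFE] = 25 * p0
        x[S.VINFI] = 2 * p0
        x[S.VAP] = 90 + 1 * p0
        x[S.VVP] = 580 + 5 * p0
        x[S.TCPH] = 0.9  # diastole (phi = 0)
        dx = self._derivs(healthy, x)
        assert np.allclose(dx[:18], 0.0, atol=1e-9)
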