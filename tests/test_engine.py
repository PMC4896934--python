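"""Closed-loop engine: determinism, conservation, convergence, numerics."""
import numpy as np
import pandas as pd
import pytest

import cardioresp as cr
from cardioresp import gas as G
from cardioresp.protocol import oxygen_uptake


def _short(dur=30.0, dt=2.5e-4):
    return cr.NumericalSettings(stage_duration=dur, dt=dt)


class TestDeterminism:
    def test_identical_runs_are_bit_identical(self, healthy):
        num = _short(20.0)
        a = cr.simulate(healthy, cr.rest_protocol(), num)
        b = cr.simulate(healthy, cr.rest_protocol(), num)
        assert np.array_equal(a.cycles.to_numpy(), b.cycles.to_numpy())
        assert np.array_equal(a.time_series.to_numpy(),
                              b.time_series.to_numpy())


class TestConservation:
    def test_blood_volume_drift_below_1e6(self, healthy_graded, hf_graded):
        for rec in (healthy_graded, hf_graded):
            v = rec.cycles["v_total"].to_numpy()
            v0 = rec.profile.blood_per_kg * rec.profile.weight
            assert np.max(np.abs(v - v0)) / v0 < 1e-6

    def test_fick_closure_every_stage(self, healthy_graded, hf_graded):
        # cycle-mean CO x central a-v O2 difference equals the prescribed
        # whole-body oxygen uptake within 2% at every workload
        for rec in (healthy_graded, hf_graded):
            for s in cr.steady_state_summary(rec):
                expected = oxygen_uptake(s.wl, rec.profile).total_vo2
                assert s.vo2_fick == pytest.approx(expected, rel=0.02), s.wl

    def test_co2_output_matches_rq_times_vo2(self, healthy_graded):
        # venous-arterial CO2 content difference times flow = RQ * VO2
        for s_wl in (0.0, 73.0):
            tail = healthy_graded.cycles.query("wl == @s_wl").tail(15)
            m = tail.mean(numeric_only=True)
            vco2 = m["co"] * 0.6 * (m["c_ven_co2"] - m["c_art_co2"])
            drive = oxygen_uptake(s_wl, healthy_graded.profile)
            assert vco2 == pytest.approx(drive.rq * drive.total_vo2,
                                         rel=0.03)


class TestSteadyState:
    def test_every_stage_converges(self, healthy_summaries, hf_summaries):
        for s in list(healthy_summaries) + list(hf_summaries):
            assert s.converged, f"stage {s.wl} W did not converge"

    def test_exercise_response_directions(self, healthy_summaries):
        rest, peak = healthy_summaries[0], healthy_summaries[-1]
        assert peak.hr > rest.hr
        assert peak.co > rest.co
        assert peak.q_leg > rest.q_leg
        assert peak.tpr < rest.tpr
        assert peak.vent > rest.vent
        assert peak.avdiff_central > rest.avdiff_central
        assert peak.elmax > rest.elmax
        # splanchnic reservoir empties into the central circulation
        assert peak.v_splanchnic < rest.v_splanchnic + 100.0

    def test_hf_is_impaired_relative_to_healthy(self, healthy_summaries,
                                                hf_summaries):
        h, f = healthy_summaries[-1], hf_summaries[-1]
        assert f.q_leg < h.q_leg          # lower exercising-region perfusion
        assert f.vent > h.vent            # hyperventilation
        assert f.elmax < h.elmax          # blunted inotropic response

    def test_monotone_workload_trends(self, healthy_summaries):
        hr = [s.hr for s in healthy_summaries]
        co = [s.co for s in healthy_summaries]
        vent = [s.vent for s in healthy_summaries]
        assert all(b > a for a, b in zip(hr, hr[1:]))
        assert all(b > a for a, b in zip(co, co[1:]))
        assert all(b > a for a, b in zip(vent, vent[1:]))


class TestSignals:
    def test_aortic_valve_flow_never_negative(self, healthy_graded):
        assert (healthy_graded.time_series["q_av"] >= 0.0).all()

    def test_arterial_and_alveolar_o2_track_each_other(self, healthy_graded):
        # equilibrated pulmonary end-capillary blood, small shunt: arterial
        # content stays close to the alveolar-equilibrium content
        tail = healthy_graded.cycles.tail(15).mean(numeric_only=True)
        c_alv = G.o2_content(tail["po2alv"])
        assert tail["c_art_o2"] == pytest.approx(c_alv, rel=0.03)

    def test_pintr_swings_widen_with_exercise(self, healthy_graded):
        ts = healthy_graded.time_series
        rest = ts[ts.wl == 0.0].tail(4000)["pintr"]
        peak = ts[ts.wl == 73.0].tail(4000)["pintr"]
        assert peak.max() - peak.min() > rest.max() - rest.min()


class TestNumerics:
    def test_step_halving_changes_summaries_below_1pct(self, healthy):
        sched = cr.rest_protocol()
        res = {}
        for dt in (2.5e-4, 1.25e-4):
            rec = cr.simulate(healthy, sched, _short(60.0, dt))
            m = rec.cycles.tail(10).mean(numeric_only=True)
            res[dt] = (m["map"], m["co"])
        for a, b in zip(res[2.5e-4], res[1.25e-4]):
            assert abs(a - b) / abs(b) < 0.01

    def test_divergence_raises_with_diagnostics(self, healthy):
        with pytest.raises(FloatingPointError, match="diverged"):
            cr.simulate(healthy, cr.rest_protocol(), _short(10.0, dt=0.05))

    def test_zero_duration_schedule_yields_empty_record(self, healthy):
        rec = cr.simulate(healthy, cr.rest_protocol(), _short(0.0))
        assert len(rec.cycles) == 0 and len(rec.time_series) == 0


class TestExport:
    def test_csv_round_trip_and_summary_json(self, healthy, tmp_path):
        rec = cr.simulate(healthy, cr.rest_protocol(), _short(20.0))
        paths = cr.export(rec, tmp_path)
        again = pd.read_csv(paths["cycles"])
        pd.testing.assert_frame_equal(again, rec.cycles)
        import json
        payload = json.loads(paths["summary"].read_text())
        assert payload["condition"] == "healthy"
        assert "0W" in payload["stages"]
        assert payload["units"]["co"] == "l/min"
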