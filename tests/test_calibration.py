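import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahva.calibration import (CalibrationReport, _sim_metrics_for_targets,
                               calibrate_ventricular, distribute_outlets,
                               outlets_total_C, outlets_total_R,
                               relative_errors, simulate_stage1,
                               update_initial_pressure, update_total_C,
                               update_total_R)
from pahva.circulation import WindkesselParams, default_params
from pahva.datamodel import Waveform


class TestRelativeErrors:
    def test_ten_percent(self):
        assert relative_errors({"x": 100.0}, {"x": 90.0})["x"] == \
            pytest.approx(10.0)

    def test_exact_match(self):
        assert relative_errors({"x": 42.0}, {"x": 42.0})["x"] == 0.0

    def test_hand_value(self):
        assert relative_errors({"p": 59.4}, {"p": 62.4})["p"] == \
            pytest.approx(5.0505, abs=1e-3)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            relative_errors({"x": 0.0}, {"x": 1.0})


class TestUpdateFormulas:
    def test_total_r_fixed_point(self):
        assert update_total_R(1.0, 90.0, 90.0, 80.0) == 1.0

    def test_total_r_hand_value(self):
        assert update_total_R(1.0, 90.0, 80.0, 80.0) == pytest.approx(1.125)

    def test_total_r_direction(self):
        assert update_total_R(1.0, 80.0, 90.0, 80.0) < 1.0

    def test_total_c_fixed_point(self):
        assert update_total_C(2.0, 40.0, 40.0) == 2.0

    def test_total_c_hand_values(self):
        assert update_total_C(2.0, 40.0, 50.0) == pytest.approx(1.6)
        assert update_total_C(1.0, 40.0, 30.0) == pytest.approx(4.0 / 3.0)

    def test_initial_pressure_fixed_point(self):
        assert update_initial_pressure(10.0, 1.0, 1.0, 1.0, 1.0) == 10.0

    def test_initial_pressure_symmetry(self):
        assert update_initial_pressure(10.0, 0.9, 1.0, 1.1, 1.0) == \
            pytest.approx(10.0)

    def test_initial_pressure_hand_value(self):
        assert update_initial_pressure(10.0, 1.2, 1.0, 1.0, 1.0) == \
            pytest.approx(11.0)

    @settings(max_examples=30, deadline=None)
    @given(rt=st.floats(0.1, 5.0), p=st.floats(10.0, 120.0),
           q=st.floats(20.0, 150.0), ct=st.floats(0.2, 5.0),
           pp=st.floats(5.0, 80.0))
    def test_matched_data_is_fixed_point(self, rt, p, q, ct, pp):
        assert update_total_R(rt, p, p, q) == rt
        assert update_total_C(ct, pp, pp) == ct
        assert update_initial_pressure(p, q, q, pp, pp) == p


class TestDistributeOutlets:
    def test_identity_ratio(self):
        outs = [WindkesselParams(0.1, 1.0, 0.5)]
        new = distribute_outlets(outs, 1.0, 1.0)
        assert new[0].r_prox == 0.1 and new[0].c == 1.0

    def test_parallel_total_scales(self):
        outs = [WindkesselParams(0.5, 1.0, 0.5),
                WindkesselParams(0.5, 1.0, 0.5)]
        new = distribute_outlets(outs, 1.5, 1.0)
        assert outlets_total_R(new) == pytest.approx(0.75)

    def test_prox_dist_split_preserved(self):
        outs = [WindkesselParams(0.1, 1.0, 0.4)]
        new = distribute_outlets(outs, 2.0, 1.0)
        assert new[0].r_prox / new[0].r_dist == pytest.approx(0.25)

    def test_compliance_sums(self):
        outs = [WindkesselParams(0.1, 1.0, 0.4),
                WindkesselParams(0.1, 3.0, 0.4)]
        assert outlets_total_C(distribute_outlets(outs, 1.0, 0.5)) == \
            pytest.approx(2.0)


class TestStage1:
    def test_imposed_flow_reaches_windkessel_steady_state(self):
        """With a constant inflow the root pressure must settle at
        P_out + Q * R_total (pure resistive steady state)."""
        T = 0.8
        flow = Waveform(np.full(40, 80.0), T)
        outlets = [WindkesselParams(0.2, 1.0, 0.8)]
        out = simulate_stage1(flow, 0.02, 0.5, outlets, p_out=5.0)
        assert out["mean_pressure"] == pytest.approx(5.0 + 80.0 * 1.0,
                                                     rel=0.01)
        assert out["pulse_pressure"] < 0.5

    def test_pulsatile_flow_pulse_decreases_with_compliance(self):
        T = 0.8
        t40 = np.arange(40) * T / 40
        flow = Waveform(80 + 60 * np.sin(2 * np.pi * t40 / T), T)
        outs_soft = [WindkesselParams(0.2, 2.0, 0.8)]
        outs_stiff = [WindkesselParams(0.2, 0.5, 0.8)]
        pp_soft = simulate_stage1(flow, 0.02, 0.5, outs_soft, 5.0)["pulse_pressure"]
        pp_stiff = simulate_stage1(flow, 0.02, 0.5, outs_stiff, 5.0)["pulse_pressure"]
        assert pp_stiff > pp_soft


class TestVentricularCalibration:
    def test_conflicting_targets_rejected(self):
        with pytest.raises(ValueError, match="ESV >= EDV"):
            calibrate_ventricular({"RV_EDV": 80.0, "RV_ESV": 90.0})

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_ventricular({"not_a_target": 1.0})

    def test_edv_target_direction(self, default_sim):
        """Raising the EDV target must raise the mapped venous resting
        volume (more blood loaded upstream of that ventricle)."""
        base = _sim_metrics_for_targets(default_sim)
        p0 = default_sim.params
        out_hi, _ = calibrate_ventricular(
            {"RV_EDV": base["RV_EDV"] * 1.3}, params0=p0, max_sweeps=2,
            sim_kwargs={"max_cycles": 6})
        out_lo, _ = calibrate_ventricular(
            {"RV_EDV": base["RV_EDV"] * 0.8}, params0=p0, max_sweeps=2,
            sim_kwargs={"max_cycles": 6})
        assert out_hi.vsv0 > p0.vsv0
        assert out_lo.vsv0 < p0.vsv0

    def test_report_structure(self, default_sim):
        base = _sim_metrics_for_targets(default_sim)
        _, rep = calibrate_ventricular(
            {"RV_EDV": base["RV_EDV"]}, params0=default_sim.params,
            max_sweeps=2, sim_kwargs={"max_cycles": 6})
        assert isinstance(rep, CalibrationReport)
        assert rep.iterations >= 1
        assert rep.history and "RV_EDV" in rep.history[0][1]
        assert rep.converged == (rep.max_error() < 10.0)
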