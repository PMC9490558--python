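import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from pahva.datamodel import Waveform
from pahva.elastance import (ElastanceSeries, TwoHillParams,
                             adjust_volume_waveform, elastance_series,
                             fit_two_hill, l2_discrepancy, two_hill)
from pahva.pv_alignment import PVLoop

T = 0.8
REF = TwoHillParams(e_max=2.0, e_min=0.05, m1=1.32, m2=27.4,
                    tau1=0.269 * T, tau2=0.452 * T, period=T)


def _refined_max(params):
    grid = np.linspace(0, params.period, 4001)
    vals = two_hill(grid, params)
    i = int(np.argmax(vals))
    res = minimize_scalar(lambda t: -two_hill(t, params),
                          bounds=(grid[max(i - 1, 0)], grid[min(i + 1, 4000)]),
                          method="bounded", options={"xatol": 1e-13})
    return -res.fun


class TestTwoHill:
    def test_value_at_zero_is_emin(self):
        assert two_hill(0.0, REF) == pytest.approx(REF.e_min, abs=1e-12)

    def test_peak_equals_emax(self):
        assert _refined_max(REF) == pytest.approx(REF.e_max, abs=1e-9)

    def test_matches_independent_evaluation(self):
        """Independent oracle: evaluate the two-sigmoid product and its
        normalization directly, without the library's table machinery."""
        t = 0.3 * T

        def shape(u):
            g1 = (u / REF.tau1) ** REF.m1
            g2 = (u / REF.tau2) ** REF.m2
            return (g1 / (1 + g1)) / (1 + g2)

        res = minimize_scalar(lambda u: -shape(u), bounds=(1e-9, T),
                              method="bounded", options={"xatol": 1e-13})
        k = (REF.e_max - REF.e_min) / (-res.fun)
        expected = k * shape(t) + REF.e_min
        assert two_hill(t, REF) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(e_max=st.floats(0.3, 5.0), e_min=st.floats(0.01, 0.2),
           m1=st.floats(0.8, 4.0), m2=st.floats(5.0, 40.0),
           f1=st.floats(0.15, 0.4), f2=st.floats(0.45, 0.7))
    def test_bounds_property(self, e_max, e_min, m1, m2, f1, f2):
        p = TwoHillParams(e_max, e_min, m1, m2, f1 * T, f2 * T, T)
        assert two_hill(0.0, p) == pytest.approx(e_min, abs=1e-10)
        assert _refined_max(p) == pytest.approx(e_max, abs=1e-8 * e_max)
        tt = np.linspace(0, T, 500)
        vals = two_hill(tt, p)
        assert np.all(vals >= e_min - 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TwoHillParams(0.05, 2.0, 1.0, 20.0, 0.2, 0.4, T)


class TestFitTwoHill:
    def test_noiseless_recovery_within_1pct(self):
        t30 = np.arange(30) * T / 30
        series = ElastanceSeries(two_hill(t30, REF), t30)
        fit, rmse = fit_two_hill(series, T)
        for attr in ("e_max", "e_min", "m1", "m2", "tau1", "tau2"):
            assert getattr(fit, attr) == pytest.approx(
                getattr(REF, attr), rel=0.01), attr
        assert rmse <= 1e-6

    def test_noisy_fit_rmse_bound(self):
        rng = np.random.default_rng(5)
        t30 = np.arange(30) * T / 30
        clean = two_hill(t30, REF)
        noisy = clean * (1 + rng.normal(0, 0.02, 30))
        fit, rmse = fit_two_hill(ElastanceSeries(noisy, t30), T)
        assert rmse <= 0.03 * REF.e_max

    def test_constant_series_degenerates_with_warning(self):
        t30 = np.arange(30) * T / 30
        with pytest.warns(UserWarning, match="constant"):
            fit, _ = fit_two_hill(ElastanceSeries(np.full(30, 1.5), t30), T)
        assert fit.e_max == pytest.approx(fit.e_min, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_two_hill(ElastanceSeries(np.ones(5), np.arange(5.0)), T)


class TestElastanceSeries:
    def test_pointwise_ratio(self):
        loop = PVLoop(np.full(30, 80.0), np.full(30, 40.0), T)
        out = elastance_series(loop)
        np.testing.assert_allclose(out.e_i, 2.0)

    def test_recovers_forward_simulated_elastance(self):
        t30 = np.arange(30) * T / 30
        e = two_hill(t30, REF)
        v = 120 - 50 * np.sin(np.pi * t30 / T)  # any positive volume course
        loop = PVLoop(e * v, v, T)
        np.testing.assert_allclose(elastance_series(loop).e_i, e, rtol=1e-12)

    def test_nonpositive_volume_rejected(self):
        loop = PVLoop(np.ones(30), np.linspace(-1, 50, 30), T)
        with pytest.raises(ValueError):
            elastance_series(loop)


def _cine_and_flow(sv_inflation=0.2):
    t30 = np.arange(30) * T / 30
    t_sys = 0.3
    vtrue = np.where(
        t30 < t_sys,
        120 - 60 * (1 - np.cos(np.pi * t30 / t_sys)) / 2,
        60 + 60 * (1 - np.cos(np.pi * (t30 - t_sys) / (T - t_sys))) / 2)
    cine = 120 + (vtrue - 120) * (1 + sv_inflation)
    t40 = np.arange(40) * T / 40
    flow = np.where(t40 < t_sys,
                    60 * np.pi / (2 * t_sys) * np.sin(np.pi * t40 / t_sys),
                    0.0)
    return Waveform(cine, T), Waveform(flow, T)


class TestAdjustVolume:
    def test_stroke_volume_conserved_exactly(self):
        cine, flow = _cine_and_flow(0.2)
        adj = adjust_volume_waveform(cine, flow)
        assert np.ptp(adj.values) == pytest.approx(np.ptp(cine.values),
                                                   abs=1e-9)

    def test_edv_assigned_from_cine(self):
        cine, flow = _cine_and_flow(0.2)
        adj = adjust_volume_waveform(cine, flow)
        assert adj.values[0] == pytest.approx(np.max(cine.values), abs=1e-9)

    def test_matched_shapes_near_identity(self):
        cine, flow = _cine_and_flow(0.0)
        adj = adjust_volume_waveform(cine, flow)
        # same SV and same ejection time course: output tracks the input
        assert np.max(np.abs(adj.values - cine.values)) < 1.0

    def test_splice_continuity(self):
        cine, flow = _cine_and_flow(0.2)
        adj = adjust_volume_waveform(cine, flow)
        sv = np.ptp(adj.values)
        # no jump larger than the natural per-phase excursion
        assert np.max(np.abs(np.diff(adj.values))) < 0.25 * sv

    def test_zero_pcmri_sv_rejected(self):
        cine, _ = _cine_and_flow()
        flat = Waveform(np.zeros(40), T)
        with pytest.raises(ValueError):
            adjust_volume_waveform(cine, flat)


class TestL2Discrepancy:
    def test_identical_is_zero(self):
        assert l2_discrepancy([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_value(self):
        assert l2_discrepancy([1, 2], [0, 0]) == 5.0

    def test_symmetry(self):
        a = np.random.default_rng(0).normal(size=20)
        b = np.random.default_rng(1).normal(size=20)
        assert l2_discrepancy(a, b) == pytest.approx(l2_discrepancy(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l2_discrepancy([1, 2], [1, 2, 3])
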