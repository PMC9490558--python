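import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahva.materials import (ActiveParams, MaterialState, PassiveParams,
                             SphereAfterload, SphereVentricle, active_ct,
                             active_stress, arterial_elastance, coupling,
                             eca50, espvr, passive_stress, sphere_loop,
                             sphere_pv, strain_energy)


class TestActivation:
    def test_starts_at_zero(self):
        assert active_ct(0.0, ActiveParams()) == 0.0

    def test_unity_at_peak_when_relaxation_later(self):
        p = ActiveParams(t0=0.25, tt=0.35)
        assert active_ct(0.25, p) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(t0=st.floats(0.1, 0.4), tt=st.floats(0.05, 0.5),
           tau=st.floats(0.01, 0.1))
    def test_continuity_at_relaxation_onset(self, t0, tt, tau):
        p = ActiveParams(t0=t0, tt=tt, tau=tau)
        left = active_ct(tt - 1e-9, p)
        right = active_ct(tt, p)
        assert right == pytest.approx(left, abs=1e-6)

    def test_relaxation_decays(self):
        p = ActiveParams(t0=0.25, tt=0.35, tau=0.03)
        assert active_ct(0.5, p) < active_ct(0.36, p)

    def test_invalid_t0_rejected(self):
        with pytest.raises(ValueError):
            active_ct(0.1, ActiveParams(t0=-1.0))


class TestCalciumSensitivity:
    def test_ln2_point(self):
        p = ActiveParams(b_len=4.75, l0=1.58, ca0_max=4.35)
        l = p.l0 + math.log(2.0) / p.b_len
        assert eca50(l, p) == pytest.approx(p.ca0_max, rel=1e-12)

    def test_diverges_at_zero_tension_length(self):
        p = ActiveParams()
        assert eca50(p.l0 + 1e-9, p) > 1e3

    def test_monotone_decreasing(self):
        p = ActiveParams()
        grid = np.linspace(p.l0 + 0.05, 2.4, 50)
        vals = [eca50(l, p) for l in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_below_l0_rejected(self):
        with pytest.raises(ValueError):
            eca50(1.0, ActiveParams(l0=1.58))

    def test_printed_variant_differs(self):
        p = ActiveParams()
        assert eca50(2.0, p) != eca50(2.0, p, printed_form=True)


class TestActiveStress:
    def test_zero_at_time_zero(self):
        st_ = MaterialState(strain_E=np.zeros((3, 3)), sarc_len=2.0)
        np.testing.assert_allclose(active_stress(st_, ActiveParams(), 0.0),
                                   0.0)

    def test_rank_one_dyad(self):
        st_ = MaterialState(strain_E=np.zeros((3, 3)), sarc_len=2.0)
        P = active_stress(st_, ActiveParams(t0=0.25, tt=0.35), 0.25)
        svals = np.linalg.svd(P, compute_uv=False)
        assert svals[0] > 0 and np.all(svals[1:] < 1e-12 * svals[0])

    def test_half_max_at_matched_calcium(self):
        p = ActiveParams(t0=0.25, tt=0.35)
        l = p.l0 + math.log(2.0) / p.b_len  # ECa50 == Ca0 here
        st_ = MaterialState(strain_E=np.zeros((3, 3)), sarc_len=l)
        P = active_stress(st_, p, 0.25)
        assert P[0, 0] == pytest.approx(p.t_ref / 2.0, rel=1e-9)


def _fd_stress(state, params, h=1e-6):
    """Central finite differences of W, treating symmetric pairs jointly."""
    E = state.strain_E
    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Ep, Em = E.copy(), E.copy()
            if i == j:
                Ep[i, i] += h
                Em[i, i] -= h
                denom = 2 * h
            else:
                Ep[i, j] += h
                Ep[j, i] += h
                Em[i, j] -= h
                Em[j, i] -= h
                denom = 4 * h
            S[i, j] = (strain_energy(MaterialState(strain_E=Ep), params)
                       - strain_energy(MaterialState(strain_E=Em), params)) \
                / denom
    return S


class TestPassiveStress:
    def test_zero_strain(self):
        st_ = MaterialState(strain_E=np.zeros((3, 3)))
        assert strain_energy(st_, PassiveParams()) == 0.0
        np.testing.assert_allclose(passive_stress(st_, PassiveParams()), 0.0)

    def test_pure_fiber_strain_hand_value(self):
        E = np.zeros((3, 3))
        E[0, 0] = 0.1
        params = PassiveParams(c_scale=1.0, b_ff=20.0, b_xx=5.0, b_fx=5.0)
        S = passive_stress(MaterialState(strain_E=E), params)
        assert S[0, 0] == pytest.approx(math.exp(0.2) * 20.0 * 0.1, rel=1e-12)
        assert S[0, 0] == pytest.approx(2.443, abs=1e-3)
        assert np.all(S[np.triu_indices(3, 1)] == 0)

    def test_gradient_consistency(self):
        rng = np.random.default_rng(11)
        params = PassiveParams()
        for _ in range(10):
            A = rng.normal(0.0, 0.05, (3, 3))
            st_ = MaterialState(strain_E=0.5 * (A + A.T))
            S = passive_stress(st_, params)
            np.testing.assert_allclose(S, _fd_stress(st_, params), atol=1e-6)


class TestSphereVentricle:
    def test_zero_pressure_at_reference(self):
        v = SphereVentricle(cavity_v=40.0, wall_v=100.0)
        assert sphere_pv(v, 0.5, activation=False,
                         cavity_v=v.ref_cavity_v) == pytest.approx(0.0)

    def test_laplace_linearity(self):
        v = SphereVentricle(cavity_v=60.0, wall_v=100.0)
        p1 = sphere_pv(v, 0.5, activation=False, cavity_v=60.0)
        v.passive = PassiveParams(c_scale=2 * v.passive.c_scale,
                                  b_ff=v.passive.b_ff, b_xx=v.passive.b_xx,
                                  b_fx=v.passive.b_fx)
        assert sphere_pv(v, 0.5, activation=False, cavity_v=60.0) == \
            pytest.approx(2 * p1, rel=1e-9)

    def test_passive_inflation_monotone_convex(self):
        """Exponential strain energy makes the inflation curve stiffen:
        monotone everywhere, convex once past the near-reference region
        where the Laplace h/r factor still dominates."""
        v = SphereVentricle(cavity_v=40.0, wall_v=100.0)
        vols = np.linspace(40.0, 80.0, 20)
        p = np.array([sphere_pv(v, 0.5, activation=False, cavity_v=x)
                      for x in vols])
        assert np.all(np.diff(p) > 0)
        assert np.all(np.diff(p, 2)[1:] > 0)
        assert p[-1] - p[-2] > 3 * (p[1] - p[0])

    def test_nonpositive_volume_rejected(self):
        v = SphereVentricle(cavity_v=40.0, wall_v=100.0)
        with pytest.raises(ValueError):
            sphere_pv(v, 0.1, cavity_v=-1.0)

    def test_contractility_raises_espvr(self):
        """Doubling the reference tension must steepen the sphere's
        end-systolic pressure-volume relation."""
        def slope(t_ref):
            pts = []
            for p_fill in (8.0, 12.0, 16.0):
                v = SphereVentricle(cavity_v=50.0, wall_v=100.0,
                                    active=ActiveParams(t_ref=t_ref))
                out = sphere_loop(v, SphereAfterload(p_preload=p_fill),
                                  max_cycles=10)
                pts.append((out["v_es"], out["p_es"]))
            vv, pp = np.array(pts).T
            return np.polyfit(vv, pp, 1)[0]

        assert slope(60.0) > 0
        assert slope(120.0) > slope(60.0)


class TestCouplingMetrics:
    def test_arterial_elastance(self):
        assert arterial_elastance(80.0, 40.0) == pytest.approx(2.0)

    def test_coupling_ratio(self):
        assert coupling(1.5, 2.0) == pytest.approx(0.75)

    def test_scale_invariance(self):
        assert coupling(1.5 * 3, 2.0 * 3) == pytest.approx(coupling(1.5, 2.0))

    def test_zero_sv_rejected(self):
        with pytest.raises(ValueError):
            arterial_elastance(80.0, 0.0)
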