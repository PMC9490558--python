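"""Closed-loop lumped-parameter (0D) cardiopulmonary circulation.

Four elastance chambers (two atria, two ventricles with a dynamic source
resistance), four valves, aortic and pulmonary root R-C segments, arterial
Windkessel beds with a configurable number of outlets, and systemic and
pulmonary venous Windkessels closing the loop.  Every storage element is a
volume state, so total blood volume is conserved by construction; valve
branches with inductance carry a flow state.

Ventricular pressure follows the elastance-with-source-resistance law

    P = E(t) * (V - V0) * (1 - ks * Q_out),

where E(t) is a two-Hill elastance for the ventricles and a single raised-
cosine bump for the atria.  Mitral and tricuspid valves are smooth diodes
(flow strictly non-negative); aortic and pulmonary valves are dynamically
controlled resistors in series with an inductor, whose resistance blends
logistically from an open value to a large closing value as the pressure
gradient reverses -- this reproduces post-systolic flow reversal and
non-zero diastolic flow.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .elastance import TwoHillParams, two_hill
from .units import BLOOD_DENSITY_G_MM3, BLOOD_VISCOSITY_G_MMS

_N_TAB = 4096  # elastance lookup-table resolution per cycle


@dataclass(frozen=True)
class AtrialElastance:
    """Single raised-cosine atrial elastance bump.

    Active over [t_onset, t_onset + width) (times may wrap around the
    cycle); baseline e_min elsewhere.
    """

    e_max: float
    e_min: float
    t_onset: float
    width: float
    period: float

    def value(self, t):
        t = np.asarray(t, dtype=float)
        phase = np.mod(t - self.t_onset, self.period)
        bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / self.width))
        return np.where(phase < self.width,
                        self.e_min + (self.e_max - self.e_min) * bump,
                        self.e_min)


@dataclass
class ChamberParams:
    elastance: object        # TwoHillParams or AtrialElastance
    v0: float = 0.0          # ml, unloaded volume
    ks: float = 0.0          # s/ml, source-resistance coefficient

    def __post_init__(self) -> None:
        if self.v0 < 0 or self.ks < 0:
            raise ValueError("v0 and ks must be non-negative")


@dataclass
class ValveParams:
    kind: str                      # "diode" or "dynamic"
    r_open: float                  # mmHg*s/ml
    inductance: float = 0.0        # mmHg*s^2/ml
    r_closed_factor: float = 5e3   # closing resistance multiplier
    dp_width: float = 1.0          # mmHg, logistic transition width

    def __post_init__(self) -> None:
        if self.r_open <= 0 or self.inductance < 0:
            raise ValueError("need r_open > 0 and inductance >= 0")


@dataclass
class WindkesselParams:
    r_prox: float
    c: float
    r_dist: float
    p_ref: float = 0.0
    v_rest: float = 0.0   # ml, resting (unstressed) volume

    def __post_init__(self) -> None:
        if min(self.r_prox, self.c, self.r_dist) <= 0:
            raise ValueError("Windkessel parameters must be positive")


@dataclass
class RootParams:
    """Arterial root / central segment: series resistance into a lumped
    compliance (the 0D surrogate for the image-resolved central arteries)."""

    r: float
    c: float
    v_rest: float = 0.0


@dataclass
class CirculationParams:
    chambers: dict                 # LA, LV, RA, RV -> ChamberParams
    valves: dict                   # mitral, aortic, tricuspid, pulmonary
    roots: dict                    # aortic, pulmonary -> RootParams
    beds: dict                     # systemic_art/pulmonary_art -> list[WK];
                                   # systemic_ven/pulmonary_ven -> WK
    period: float
    initial_pressures: dict = field(default_factory=dict)
    initial_chamber_volumes: dict = field(default_factory=dict)
    blood: tuple = (BLOOD_DENSITY_G_MM3, BLOOD_VISCOSITY_G_MMS)

    def copy(self) -> "CirculationParams":
        return copy.deepcopy(self)

    @property
    def vsv0(self) -> float:
        return self.beds["systemic_ven"].v_rest

    @vsv0.setter
    def vsv0(self, v: float) -> None:
        self.beds["systemic_ven"].v_rest = v

    @property
    def vpv0(self) -> float:
        return self.beds["pulmonary_ven"].v_rest

    @vpv0.setter
    def vpv0(self, v: float) -> None:
        self.beds["pulmonary_ven"].v_rest = v

    def arterial_outlets(self, side: str):
        bed = self.beds[f"{side}_art"]
        return bed if isinstance(bed, list) else [bed]


def chamber_pressure(chamber: ChamberParams, v: float, t: float,
                     q_out: float = 0.0) -> float:
    """Chamber pressure P = E(t) * (v - v0) * (1 - ks * q_out)."""
    if v < 0:
        raise ValueError("volume must be non-negative")
    el = chamber.elastance
    e = two_hill(t, el) if isinstance(el, TwoHillParams) else el.value(t)
    return float(e) * (v - chamber.v0) * (1.0 - chamber.ks * q_out)


def default_params(period: float = 0.8) -> CirculationParams:
    """A healthy-adult-like closed-loop parameter set (documented fixture).

    Chosen to produce physiological pressures (systemic ~115/70 mmHg,
    pulmonary ~25/10 mmHg), cardiac output ~4-6 L/min and ejection
    fractions in the 50-70% range at a 75 bpm cycle.
    """
    T = period

    def vent(e_max, e_min):
        return TwoHillParams(e_max=e_max, e_min=e_min, m1=1.32, m2=27.4,
                             tau1=0.269 * T, tau2=0.452 * T, period=T)

    chambers = {
        "LA": ChamberParams(AtrialElastance(0.28, 0.16, 0.80 * T, 0.17 * T, T), v0=4.0),
        "LV": ChamberParams(vent(2.4, 0.06), v0=10.0, ks=2e-4),
        "RA": ChamberParams(AtrialElastance(0.22, 0.12, 0.80 * T, 0.17 * T, T), v0=4.0),
        "RV": ChamberParams(vent(0.55, 0.045), v0=10.0, ks=2e-4),
    }
    valves = {
        "mitral": ValveParams("diode", r_open=0.004),
        "aortic": ValveParams("dynamic", r_open=0.006, inductance=5e-4),
        "tricuspid": ValveParams("diode", r_open=0.004),
        "pulmonary": ValveParams("dynamic", r_open=0.0045, inductance=3e-4),
    }
    roots = {
        "aortic": RootParams(r=0.03, c=0.45),
        "pulmonary": RootParams(r=0.012, c=1.6),
    }
    beds = {
        "systemic_art": [WindkesselParams(0.10, 0.50, 1.80),
                         WindkesselParams(0.10, 0.50, 1.80)],
        "pulmonary_art": [WindkesselParams(0.030, 1.20, 0.140),
                          WindkesselParams(0.030, 1.20, 0.140)],
        "systemic_ven": WindkesselParams(0.010, 60.0, 0.030, v_rest=2400.0),
        "pulmonary_ven": WindkesselParams(0.005, 13.0, 0.006, v_rest=350.0),
    }
    initial_pressures = {
        "ao_root": 75.0, "sa": 72.0, "sv": 7.0,
        "pa_root": 16.0, "pa": 15.0, "pv": 10.0,
    }
    initial_chamber_volumes = {"LA": 60.0, "LV": 130.0, "RA": 60.0, "RV": 130.0}
    return CirculationParams(chambers, valves, roots, beds, T,
                             initial_pressures, initial_chamber_volumes)


class _Model:
    """Prepared model: state indexing, elastance lookup tables, fast RHS."""

    def __init__(self, p: CirculationParams):
        self.p = p
        T = p.period
        self.T = T
        self.sa = p.arterial_outlets("systemic")
        self.pa = p.arterial_outlets("pulmonary")
        nsa, npa = len(self.sa), len(self.pa)

        names = ["LA", "LV", "RA", "RV", "ao_root"]
        names += [f"sa_{j}" for j in range(nsa)]
        names += ["sv", "pa_root"]
        names += [f"pa_{j}" for j in range(npa)]
        names += ["pv"]
        self.vol_names = list(names)
        self.i_qav = len(names)
        self.i_qpv = len(names) + 1
        self.n_states = len(names) + 2
        self.idx = {n: i for i, n in enumerate(names)}

        # elastance lookup tables over [0, T]
        tt = np.linspace(0.0, T, _N_TAB + 1)
        self.tabs = {}
        for name in ("LA", "LV", "RA", "RV"):
            el = p.chambers[name].elastance
            e = two_hill(tt, el) if isinstance(el, TwoHillParams) else el.value(tt)
            self.tabs[name] = np.asarray(e, dtype=float)
        self._tab_scale = _N_TAB / T

        # flat scalar copies for the hot loop
        c = p.chambers
        self.v0 = [c[n].v0 for n in ("LA", "LV", "RA", "RV")]
        self.ks = [c[n].ks for n in ("LA", "LV", "RA", "RV")]
        self.valves = p.valves
        self.roots = p.roots

    # -- initial condition ------------------------------------------------
    def initial_state(self) -> np.ndarray:
        p = self.p
        ip = p.initial_pressures
        y = np.zeros(self.n_states)
        for k, name in enumerate(("LA", "LV", "RA", "RV")):
            y[k] = p.initial_chamber_volumes.get(name, 80.0)
        ra, rp = p.roots["aortic"], p.roots["pulmonary"]
        y[self.idx["ao_root"]] = ra.v_rest + ra.c * ip.get("ao_root", 80.0)
        y[self.idx["pa_root"]] = rp.v_rest + rp.c * ip.get("pa_root", 15.0)
        for j, wk in enumerate(self.sa):
            y[self.idx[f"sa_{j}"]] = wk.v_rest + wk.c * ip.get("sa", 75.0)
        for j, wk in enumerate(self.pa):
            y[self.idx[f"pa_{j}"]] = wk.v_rest + wk.c * ip.get("pa", 15.0)
        sv, pv = p.beds["systemic_ven"], p.beds["pulmonary_ven"]
        y[self.idx["sv"]] = sv.v_rest + sv.c * ip.get("sv", 6.0)
        y[self.idx["pv"]] = pv.v_rest + pv.c * ip.get("pv", 9.0)
        return y

    # -- elastance lookup -------------------------------------------------
    def _elast(self, name: str, t: float) -> float:
        x = (t % self.T) * self._tab_scale
        i = int(x)
        if i >= _N_TAB:
            i = _N_TAB - 1
        tab = self.tabs[name]
        return tab[i] + (tab[i + 1] - tab[i]) * (x - i)

    # -- valve laws -------------------------------------------------------
    @staticmethod
    def _diode_flow(dp: float, r: float, w: float = 1e-3) -> float:
        return 0.5 * (dp + math.sqrt(dp * dp + w * w)) / r

    @staticmethod
    def _dyn_resistance(dp: float, v: ValveParams) -> float:
        a = dp / v.dp_width
        if a < -40.0:
            sig = 1.0
        elif a > 40.0:
            sig = 0.0
        else:
            sig = 1.0 / (1.0 + math.exp(a))
        return v.r_open * (1.0 + (v.r_closed_factor - 1.0) * sig)

    # -- right-hand side --------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.p
        idx = self.idx
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("NaN/Inf in circulation state")
        q_av = y[self.i_qav]
        q_pvv = y[self.i_qpv]

        e_la = self._elast("LA", t)
        e_lv = self._elast("LV", t)
        e_ra = self._elast("RA", t)
        e_rv = self._elast("RV", t)
        p_la = e_la * (y[0] - self.v0[0])
        p_lv = e_lv * (y[1] - self.v0[1]) * (1.0 - self.ks[1] * q_av)
        p_ra = e_ra * (y[2] - self.v0[2])
        p_rv = e_rv * (y[3] - self.v0[3]) * (1.0 - self.ks[3] * q_pvv)

        ra, rp = self.roots["aortic"], self.roots["pulmonary"]
        p_ao = (y[idx["ao_root"]] - ra.v_rest) / ra.c
        p_par = (y[idx["pa_root"]] - rp.v_rest) / rp.c
        svk = p.beds["systemic_ven"]
        pvk = p.beds["pulmonary_ven"]
        p_sv = (y[idx["sv"]] - svk.v_rest) / svk.c + svk.p_ref
        p_pv = (y[idx["pv"]] - pvk.v_rest) / pvk.c + pvk.p_ref

        # AV valves: smooth diodes (non-negative flow)
        mv, tv = self.valves["mitral"], self.valves["tricuspid"]
        q_mv = self._diode_flow(p_la - p_lv, mv.r_open)
        q_tv = self._diode_flow(p_ra - p_rv, tv.r_open)

        # semilunar branches: dynamic resistor + root resistance + inductor
        av, pvv = self.valves["aortic"], self.valves["pulmonary"]
        dp_av = p_lv - p_ao
        dp_pv = p_rv - p_par
        r_av = self._dyn_resistance(dp_av, av) + ra.r
        r_pv = self._dyn_resistance(dp_pv, pvv) + rp.r
        dq_av = (dp_av - r_av * q_av) / av.inductance
        dq_pv = (dp_pv - r_pv * q_pvv) / pvv.inductance

        dy = np.empty(self.n_states)
        # systemic outlets
        q_sa_in_sum = 0.0
        q_sa_out_sum = 0.0
        for j, wk in enumerate(self.sa):
            pj = (y[idx[f"sa_{j}"]] - wk.v_rest) / wk.c + wk.p_ref
            qin = (p_ao - pj) / wk.r_prox
            qout = (pj - p_sv) / wk.r_dist
            dy[idx[f"sa_{j}"]] = qin - qout
            q_sa_in_sum += qin
            q_sa_out_sum += qout
        # pulmonary outlets
        q_pa_in_sum = 0.0
        q_pa_out_sum = 0.0
        for j, wk in enumerate(self.pa):
            pj = (y[idx[f"pa_{j}"]] - wk.v_rest) / wk.c + wk.p_ref
            qin = (p_par - pj) / wk.r_prox
            qout = (pj - p_pv) / wk.r_dist
            dy[idx[f"pa_{j}"]] = qin - qout
            q_pa_in_sum += qin
            q_pa_out_sum += qout

        q_sv_out = (p_sv - p_ra) / (svk.r_prox + svk.r_dist)
        q_pv_out = (p_pv - p_la) / (pvk.r_prox + pvk.r_dist)

        dy[0] = q_pv_out - q_mv           # LA
        dy[1] = q_mv - q_av               # LV
        dy[2] = q_sv_out - q_tv           # RA
        dy[3] = q_tv - q_pvv              # RV
        dy[idx["ao_root"]] = q_av - q_sa_in_sum
        dy[idx["sv"]] = q_sa_out_sum - q_sv_out
        dy[idx["pa_root"]] = q_pvv - q_pa_in_sum
        dy[idx["pv"]] = q_pa_out_sum - q_pv_out
        dy[self.i_qav] = dq_av
        dy[self.i_qpv] = dq_pv
        return dy

    # -- vectorized post-processing --------------------------------------
    def outputs(self, t: np.ndarray, Y: np.ndarray) -> tuple:
        """Pressures (mmHg) and flows (ml/s) at sampled states.

        Returns (pressures, flows) dicts of arrays matching ``t``.
        """
        p = self.p
        idx = self.idx
        q_av = Y[self.i_qav]
        q_pvv = Y[self.i_qpv]
        e = {n: np.interp(np.mod(t, self.T), np.linspace(0.0, self.T, _N_TAB + 1),
                          self.tabs[n]) for n in ("LA", "LV", "RA", "RV")}
        c = p.chambers
        P = {
            "LA": e["LA"] * (Y[0] - c["LA"].v0),
            "LV": e["LV"] * (Y[1] - c["LV"].v0) * (1.0 - c["LV"].ks * q_av),
            "RA": e["RA"] * (Y[2] - c["RA"].v0),
            "RV": e["RV"] * (Y[3] - c["RV"].v0) * (1.0 - c["RV"].ks * q_pvv),
        }
        ra, rp = self.roots["aortic"], self.roots["pulmonary"]
        P["AAo"] = (Y[idx["ao_root"]] - ra.v_rest) / ra.c
        P["MPA"] = (Y[idx["pa_root"]] - rp.v_rest) / rp.c
        svk, pvk = p.beds["systemic_ven"], p.beds["pulmonary_ven"]
        P["SV"] = (Y[idx["sv"]] - svk.v_rest) / svk.c + svk.p_ref
        P["PV"] = (Y[idx["pv"]] - pvk.v_rest) / pvk.c + pvk.p_ref

        Q = {"aortic": q_av, "pulmonary": q_pvv}
        mv, tv = self.valves["mitral"], self.valves["tricuspid"]
        dmv = P["LA"] - P["LV"]
        dtv = P["RA"] - P["RV"]
        Q["mitral"] = 0.5 * (dmv + np.sqrt(dmv * dmv + 1e-6)) / mv.r_open
        Q["tricuspid"] = 0.5 * (dtv + np.sqrt(dtv * dtv + 1e-6)) / tv.r_open
        for side, outlets, proot in (("sa", self.sa, P["AAo"]),
                                     ("pa", self.pa, P["MPA"])):
            for j, wk in enumerate(outlets):
                pj = (Y[idx[f"{side}_{j}"]] - wk.v_rest) / wk.c + wk.p_ref
                P[f"{side}_{j}"] = pj
                Q[f"{side}_{j}_in"] = (proot - pj) / wk.r_prox
                Q[f"{side}_{j}_out"] = (pj - (P["SV"] if side == "sa" else P["PV"])) / wk.r_dist
        Q["sv_out"] = (P["SV"] - P["RA"]) / (svk.r_prox + svk.r_dist)
        Q["pv_out"] = (P["PV"] - P["LA"]) / (pvk.r_prox + pvk.r_dist)
        return P, Q

    def cycle_summary(self, t: np.ndarray, Y: np.ndarray) -> dict:
        P, Q = self.outputs(t, Y)
        out = {f"P_{k}": float(np.mean(v)) for k, v in P.items()
               if k in ("AAo", "MPA", "SV", "PV")}
        out["SV_LV"] = float(np.max(Y[1]) - np.min(Y[1]))
        out["SV_RV"] = float(np.max(Y[3]) - np.min(Y[3]))
        return out


@dataclass
class SimResult:
    time: np.ndarray
    volumes: dict        # name -> ml array
    pressures: dict      # site -> mmHg array
    flows: dict          # branch -> ml/s array
    cycles_run: int
    periodicity_error: float
    converged: bool
    n_out: int
    period: float
    y_final: np.ndarray
    params: CirculationParams

    def last_cycle(self) -> "SimResult":
        s = slice(len(self.time) - self.n_out, len(self.time))
        return SimResult(
            time=self.time[s],
            volumes={k: v[s] for k, v in self.volumes.items()},
            pressures={k: v[s] for k, v in self.pressures.items()},
            flows={k: v[s] for k, v in self.flows.items()},
            cycles_run=self.cycles_run,
            periodicity_error=self.periodicity_error,
            converged=self.converged,
            n_out=self.n_out,
            period=self.period,
            y_final=self.y_final,
            params=self.params,
        )

    @property
    def total_volume(self) -> np.ndarray:
        return np.sum(np.stack(list(self.volumes.values())), axis=0)


def derivatives(state, t, params: CirculationParams) -> np.ndarray:
    """State rates of the closed-loop network (volumes then valve flows).

    Thin functional wrapper over the prepared model; state layout matches
    :meth:`_Model.initial_state`.
    """
    return _Model(params).rhs(t, np.asarray(state, dtype=float))


def simulate(params: CirculationParams, dt: float = 1e-4,
             max_cycles: int = 40, periodicity_tol: float = 1e-3,
             n_out: int = 200, y0: Optional[np.ndarray] = None,
             min_cycles: int = 3, rtol: float = 1e-6,
             atol: float = 1e-8, method: str = "BDF") -> SimResult:
    """Integrate the closed loop until cycle-to-cycle periodicity.

    Integration is adaptive and stiff-capable (BDF by default; valve
    closure gives the system fast time constants); ``dt`` bounds the
    minimum output resolution.  The run stops when relative changes in
    cycle-mean node pressures and stroke volumes between consecutive
    cycles fall below ``periodicity_tol``, or after ``max_cycles`` (the
    result is then flagged non-converged, not raised).
    """
    model = _Model(params)
    T = params.period
    y = model.initial_state() if y0 is None else np.array(y0, dtype=float)
    ts, ys = [], []
    prev = None
    perr = math.inf
    converged = False
    cycles = 0
    for k in range(max_cycles):
        t_eval = np.linspace(k * T, (k + 1) * T, n_out + 1)
        sol = solve_ivp(model.rhs, (k * T, (k + 1) * T), y, method=method,
                        t_eval=t_eval, rtol=rtol, atol=atol,
                        max_step=max(T / 20.0, dt))
        if not sol.success:
            raise RuntimeError(f"integration failed in cycle {k}: {sol.message}")
        y = sol.y[:, -1]
        ts.append(sol.t[:-1])
        ys.append(sol.y[:, :-1])
        cycles = k + 1
        summ = model.cycle_summary(sol.t, sol.y)
        if prev is not None:
            perr = max(abs(summ[key] - prev[key]) / max(abs(prev[key]), 1.0)
                       for key in summ)
            if perr < periodicity_tol and cycles >= min_cycles:
                converged = True
                prev = summ
                break
        prev = summ
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    P, Q = model.outputs(t, Y)
    volumes = {name: Y[model.idx[name]] for name in model.vol_names}
    return SimResult(time=t, volumes=volumes, pressures=P, flows=Q,
                     cycles_run=cycles, periodicity_error=float(perr),
                     converged=converged, n_out=n_out, period=T,
                     y_final=y, params=params)


def extract_metrics(result: SimResult) -> dict:
    """Hemodynamic metrics from the last full cycle of a simulation:
    mean/systolic/diastolic pressures per site, mean flows, and per-
    ventricle EDV/ESV/SV/EF.  A non-periodic result gets a warning flag."""
    lc = result.last_cycle()
    out: dict = {}
    if not result.converged:
        out["warning"] = "result not periodic at tolerance"
    for site, arr in lc.pressures.items():
        out[f"{site}_mean_pressure"] = float(np.mean(arr))
        out[f"{site}_sys_pressure"] = float(np.max(arr))
        out[f"{site}_dias_pressure"] = float(np.min(arr))
    for branch, arr in lc.flows.items():
        out[f"{branch}_mean_flow"] = float(np.mean(arr))
    for name, key in (("LV", "LV"), ("RV", "RV")):
        v = lc.volumes[key]
        edv, esv = float(np.max(v)), float(np.min(v))
        out[f"{name}_EDV"] = edv
        out[f"{name}_ESV"] = esv
        out[f"{name}_SV"] = edv - esv
        out[f"{name}_EF"] = (edv - esv) / edv * 100.0
    return out
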