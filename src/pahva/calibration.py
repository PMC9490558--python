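"""Boundary-condition design and fixed-point calibration.

Windkessel outflow parameters are tuned by fixed-point iteration: total
arterial resistance moves by the mean-pressure defect divided by mean
flow, total compliance by the pulse-pressure ratio, and both are
distributed proportionally over the outlet branches; initial nodal
pressures move by the average of the flow and pressure ratios.  The
calibration proceeds in three stages: (1) open-loop arterial bed with
imposed measured inflow, (2) open-loop bed driven by an elastance heart
(tuning preload pressure and the source-resistance coefficient), and
(3) the full closed loop.  Parameters carry forward between stages and
iteration stops when all relative errors fall below the tolerance
(default 10%).

The ventricular-model family is calibrated by damped coordinate descent
over the metric-to-parameter mapping (venous resting volumes -> EDV,
arterial resistances -> mean pressures, compliances -> pulse pressures,
peak elastance -> ESV, diastolic elastance -> EDP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .circulation import (CirculationParams, SimResult, WindkesselParams,
                          default_params, extract_metrics, simulate)
from .datamodel import ClinicalBundle, Waveform
from .elastance import l2_discrepancy

DEFAULT_TOL_PCT = 10.0


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationReport:
    iterations: int = 0
    history: list = field(default_factory=list)  # (snapshot, errors) per iter
    converged: bool = False
    final_errors: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def max_error(self) -> float:
        return max(self.final_errors.values()) if self.final_errors else math.inf


# ---------------------------------------------------------------------------
# Fixed-point update formulas
# ---------------------------------------------------------------------------

def relative_errors(targets: dict, simulated: dict) -> dict:
    """Per-metric |data - model| / |data| * 100 over the shared keys."""
    out = {}
    for key, tv in targets.items():
        if key not in simulated:
            continue
        if tv == 0:
            raise ValueError(f"target {key} is zero: relative error undefined")
        out[key] = abs((tv - simulated[key]) / tv) * 100.0
    return out


def update_total_R(rt_n: float, p_mean_target: float, p_mean_sim: float,
                   q_mean_sim: float) -> float:
    """RT^{n+1} = RT^n + (Pmean - Pmean^n)/Qmean^n."""
    if q_mean_sim <= 0:
        raise ValueError("simulated mean flow must be positive")
    return rt_n + (p_mean_target - p_mean_sim) / q_mean_sim


def update_total_C(ct_n: float, pp_target: float, pp_sim: float) -> float:
    """CT^{n+1} = CT^n * (Ppulse / Ppulse^n), the printed fixed-point form.

    Note the iteration loops below apply this with the ratio inverted
    (simulated over target), the numerically stable orientation: pulse
    pressure decreases with compliance, so a too-large simulated pulse
    requires more compliance, not less.
    """
    if pp_sim <= 0:
        raise ValueError("simulated pulse pressure must be positive")
    return ct_n * (pp_target / pp_sim)


def update_initial_pressure(p_init: float, q_target: float, q_sim: float,
                            p_target: float, p_sim: float) -> float:
    """P^{n+1} = P^n * average(Qmean/Qmean^n, Pmean/Pmean^n)."""
    if q_sim <= 0 or p_sim <= 0:
        raise ValueError("simulated means must be positive")
    return p_init * 0.5 * (q_target / q_sim + p_target / p_sim)


def distribute_outlets(outlets, rt_ratio: float, ct_ratio: float):
    """Scale every outlet's resistances by rt_ratio and compliance by
    ct_ratio (Windkessel proximal:distal split preserved)."""
    if rt_ratio <= 0 or ct_ratio <= 0:
        raise ValueError("ratios must be positive")
    return [WindkesselParams(w.r_prox * rt_ratio, w.c * ct_ratio,
                             w.r_dist * rt_ratio, w.p_ref, w.v_rest)
            for w in outlets]


def outlets_total_R(outlets) -> float:
    """Parallel combination of the outlet series resistances."""
    return 1.0 / sum(1.0 / (w.r_prox + w.r_dist) for w in outlets)


def outlets_total_C(outlets) -> float:
    return sum(w.c for w in outlets)


# ---------------------------------------------------------------------------
# Stage-1/2 open-loop surrogate circuits
# ---------------------------------------------------------------------------

def _periodic_sampler(wf: Waveform):
    vals = np.asarray(wf.values, dtype=float)
    n = len(vals)
    scale = n / wf.period

    def f(t):
        x = (t % wf.period) * scale
        i = int(x)
        if i >= n:
            i = n - 1
        j = (i + 1) % n
        w = x - i
        return vals[i] * (1.0 - w) + vals[j] * w

    return f


def simulate_stage1(flow: Waveform, root_r: float, root_c: float,
                    outlets, p_out: float, max_cycles: int = 12,
                    tol: float = 1e-3, n_out: int = 100) -> dict:
    """Open-loop arterial bed with an imposed periodic inflow.

    Returns root-node pressure statistics of the last (periodic) cycle.
    """
    T = flow.period
    q_in = _periodic_sampler(flow)
    nw = len(outlets)
    rp = [w.r_prox for w in outlets]
    rd = [w.r_dist for w in outlets]
    cs = [w.c for w in outlets]

    def rhs(t, y):
        p_root = y[0] / root_c
        dy = np.empty(nw + 1)
        q_sum = 0.0
        for j in range(nw):
            pj = y[j + 1] / cs[j]
            qj = (p_root - pj) / rp[j]
            dy[j + 1] = qj - (pj - p_out) / rd[j]
            q_sum += qj
        dy[0] = q_in(t) - q_sum
        return dy

    q_mean = float(np.mean(flow.values))
    p_guess = p_out + q_mean * outlets_total_R(outlets)
    y = np.array([root_c * p_guess] + [c * p_guess for c in cs])
    prev = None
    for k in range(max_cycles):
        tt = np.linspace(k * T, (k + 1) * T, n_out + 1)
        sol = solve_ivp(rhs, (k * T, (k + 1) * T), y, method="LSODA",
                        t_eval=tt, rtol=1e-7, atol=1e-8)
        y = sol.y[:, -1]
        p_root = sol.y[0] / root_c
        summ = (float(np.mean(p_root)), float(np.max(p_root)),
                float(np.min(p_root)))
        if prev is not None and all(
                abs(a - b) / max(abs(b), 1.0) < tol for a, b in zip(summ, prev)):
            break
        prev = summ
    return {"mean_pressure": summ[0], "sys_pressure": summ[1],
            "dias_pressure": summ[2], "pulse_pressure": summ[1] - summ[2],
            "mean_flow": q_mean, "time": sol.t - sol.t[0],
            "root_pressure": p_root}


def simulate_stage2(heart, valve, root_r: float, root_c: float, outlets,
                    p_out: float, p_fill: float, period: float,
                    r_fill: float = 0.005, max_cycles: int = 20,
                    tol: float = 1e-3, n_out: int = 100) -> dict:
    """Open-loop bed driven by an elastance chamber filling from a
    constant-pressure reservoir.  ``heart`` is a ChamberParams; ``valve``
    the semilunar ValveParams."""
    from .elastance import two_hill

    T = period
    tt_tab = np.linspace(0.0, T, 2049)
    e_tab = np.asarray(two_hill(tt_tab, heart.elastance), dtype=float)
    scale = 2048 / T
    nw = len(outlets)
    rp = [w.r_prox for w in outlets]
    rd = [w.r_dist for w in outlets]
    cs = [w.c for w in outlets]
    v0, ks = heart.v0, heart.ks
    L = valve.inductance if valve.inductance > 0 else 1e-4

    def rhs(t, y):
        x = (t % T) * scale
        i = int(x)
        if i >= 2048:
            i = 2047
        e = e_tab[i] + (e_tab[i + 1] - e_tab[i]) * (x - i)
        vv, q = y[0], y[1]
        p_v = e * (vv - v0) * (1.0 - ks * q)
        p_root = y[2] / root_c
        dp_fill = p_fill - p_v
        q_in = 0.5 * (dp_fill + math.sqrt(dp_fill * dp_fill + 1e-6)) / r_fill
        dp_v = p_v - p_root
        a = dp_v / valve.dp_width
        sig = 1.0 / (1.0 + math.exp(min(max(a, -40.0), 40.0)))
        r_v = valve.r_open * (1.0 + (valve.r_closed_factor - 1.0) * sig) + root_r
        dq = (dp_v - r_v * q) / L
        dy = np.empty(nw + 3)
        q_sum = 0.0
        for j in range(nw):
            pj = y[j + 3] / cs[j]
            qj = (p_root - pj) / rp[j]
            dy[j + 3] = qj - (pj - p_out) / rd[j]
            q_sum += qj
        dy[0] = q_in - q
        dy[1] = dq
        dy[2] = q - q_sum
        return dy

    p_guess = p_out + 60.0
    y = np.array([v0 + 120.0, 0.0, root_c * p_guess] + [c * p_guess for c in cs])
    prev = None
    for k in range(max_cycles):
        te = np.linspace(k * T, (k + 1) * T, n_out + 1)
        sol = solve_ivp(rhs, (k * T, (k + 1) * T), y, method="BDF",
                        t_eval=te, rtol=1e-6, atol=1e-8)
        y = sol.y[:, -1]
        p_root = sol.y[2] / root_c
        q_valve = sol.y[1]
        summ = (float(np.mean(p_root)), float(np.max(p_root)),
                float(np.min(p_root)), float(np.mean(q_valve)))
        if prev is not None and all(
                abs(a - b) / max(abs(b), 1.0) < tol for a, b in zip(summ, prev)):
            break
        prev = summ
    return {"mean_pressure": summ[0], "sys_pressure": summ[1],
            "dias_pressure": summ[2], "pulse_pressure": summ[1] - summ[2],
            "mean_flow": summ[3], "time": sol.t - sol.t[0],
            "flow": q_valve, "root_pressure": p_root}


# ---------------------------------------------------------------------------
# Target extraction
# ---------------------------------------------------------------------------

def targets_from_bundle(bundle: ClinicalBundle) -> dict:
    """Standard-key hemodynamic targets from a clinical bundle.

    Pressures (mmHg): MPA from the catheter waveform (or cath metrics),
    systemic from the AAo/DTA waveform; flows (ml/s) from PC-MRI.
    """
    t: dict = {}
    for site, keys in (("MPA", ("MPA",)), ("SA", ("AAo", "DTA"))):
        wf = next((bundle.pressures[k] for k in keys if k in bundle.pressures),
                  None)
        if wf is not None:
            arr = np.asarray(wf.values, dtype=float)
            t[f"{site}_mean_pressure"] = float(np.mean(arr))
            t[f"{site}_sys_pressure"] = float(np.max(arr))
            t[f"{site}_dias_pressure"] = float(np.min(arr))
            t[f"{site}_pulse_pressure"] = float(np.max(arr) - np.min(arr))
    c = bundle.record.cath_metrics if bundle.record else {}
    t.setdefault("MPA_mean_pressure", c.get("mpap_mmhg"))
    t.setdefault("MPA_sys_pressure", c.get("pa_systolic_mmhg"))
    for site in ("AAo", "MPA"):
        if site in bundle.flows:
            t[f"{site}_mean_flow"] = float(np.mean(bundle.flows[site].values))
    for side in ("LV", "RV"):
        if side in bundle.volumes:
            v = np.asarray(bundle.volumes[side].values, dtype=float)
            t[f"{side}_EDV"] = float(np.max(v))
            t[f"{side}_ESV"] = float(np.min(v))
    return {k: v for k, v in t.items() if v is not None}


def _sim_metrics_for_targets(res: SimResult) -> dict:
    m = extract_metrics(res)
    lc = res.last_cycle()
    sim = {
        "MPA_mean_pressure": m["MPA_mean_pressure"],
        "MPA_sys_pressure": m["MPA_sys_pressure"],
        "MPA_dias_pressure": m["MPA_dias_pressure"],
        "MPA_pulse_pressure": m["MPA_sys_pressure"] - m["MPA_dias_pressure"],
        "SA_mean_pressure": m["AAo_mean_pressure"],
        "SA_sys_pressure": m["AAo_sys_pressure"],
        "SA_dias_pressure": m["AAo_dias_pressure"],
        "SA_pulse_pressure": m["AAo_sys_pressure"] - m["AAo_dias_pressure"],
        "AAo_mean_flow": m["aortic_mean_flow"],
        "MPA_mean_flow": m["pulmonary_mean_flow"],
        "LV_EDV": m["LV_EDV"], "LV_ESV": m["LV_ESV"],
        "RV_EDV": m["RV_EDV"], "RV_ESV": m["RV_ESV"],
    }
    for side in ("LV", "RV"):
        v = lc.volumes[side]
        p = lc.pressures[side]
        sim[f"{side}_ESP"] = float(np.max(p))
        # end-diastole sits on a flat volume plateau (isovolumetric
        # contraction); take the lowest pressure on the near-EDV plateau
        # rather than the pressure at argmax, which can land mid-upstroke
        edv, esv = np.max(v), np.min(v)
        plateau = v >= esv + 0.995 * (edv - esv)
        sim[f"{side}_EDP"] = float(np.min(p[plateau]))
    return sim


# ---------------------------------------------------------------------------
# Arterial-model calibration (stages 1-3)
# ---------------------------------------------------------------------------

def _stage1_side(flow: Waveform, p_mean_t: float, p_pulse_t: float,
                 root_r: float, root_c: float, outlets, p_out: float,
                 tol_pct: float, max_iter: int, report: CalibrationReport,
                 label: str):
    """Iterate Eqs 4-6 for one side; returns calibrated outlets."""
    damp = 1.0
    worse = 0
    prev_err = math.inf
    for it in range(max_iter):
        sim = simulate_stage1(flow, root_r, root_c, outlets, p_out)
        errs = relative_errors(
            {f"{label}_mean_pressure": p_mean_t,
             f"{label}_pulse_pressure": p_pulse_t},
            {f"{label}_mean_pressure": sim["mean_pressure"],
             f"{label}_pulse_pressure": sim["pulse_pressure"]})
        report.history.append(({f"{label}_RT": outlets_total_R(outlets),
                                f"{label}_CT": outlets_total_C(outlets)},
                               errs))
        report.iterations += 1
        err = max(errs.values())
        if err < tol_pct:
            return outlets, errs
        if err > prev_err:
            worse += 1
            if worse >= 3:
                damp = 0.5
                report.notes.append(f"{label}: damping engaged at iter {it}")
        else:
            worse = 0
        prev_err = err
        rt = outlets_total_R(outlets)
        ct = outlets_total_C(outlets)
        rt_new = update_total_R(rt, p_mean_t, sim["mean_pressure"],
                                sim["mean_flow"])
        rt_new = max(rt_new, 0.05 * rt)
        # stable orientation of the pulse-pressure fixed point (see
        # update_total_C): compliance grows when the simulated pulse is
        # too large
        ct_new = update_total_C(ct, sim["pulse_pressure"], p_pulse_t)
        rt_ratio = (rt_new / rt) ** damp
        ct_ratio = (ct_new / ct) ** damp
        outlets = distribute_outlets(outlets, rt_ratio, ct_ratio)
    return outlets, errs


def calibrate_arterial(bundle: ClinicalBundle, stage: int = 3,
                       tol: float = DEFAULT_TOL_PCT,
                       params0: CirculationParams = None,
                       max_iter: int = 30,
                       sim_kwargs: dict = None) -> tuple:
    """Three-stage arterial boundary-condition calibration.

    Stage 1 tunes the systemic and pulmonary Windkessels (Eqs for total
    resistance/compliance with proportional outlet distribution) against
    mean and pulse pressures under the measured inflows.  Stage 2 swaps
    the imposed inflows for elastance hearts and additionally tunes
    preload pressures (ratio-average update) and the source-resistance
    coefficient ks (flow-shape L2).  Stage 3 closes the loop and re-tunes
    resistances, compliances and initial venous pressures until all
    relative errors are below ``tol`` percent.

    Returns ``(CirculationParams, CalibrationReport)``.
    """
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    targets = targets_from_bundle(bundle)
    period = next(iter(bundle.flows.values())).period if bundle.flows else 0.8
    params = (params0.copy() if params0 is not None
              else default_params(period))
    report = CalibrationReport()
    sim_kwargs = dict(sim_kwargs or {})

    p_out_sys, p_out_pulm = 6.0, 9.0
    sides = (
        ("SA", "AAo", "systemic_art", "aortic", p_out_sys),
        ("MPA", "MPA", "pulmonary_art", "pulmonary", p_out_pulm),
    )

    # ---- Stage 1: imposed inflows ------------------------------------
    for label, flow_site, bed, root, p_out in sides:
        if flow_site not in bundle.flows:
            continue
        if f"{label}_mean_pressure" not in targets:
            continue
        outlets, _ = _stage1_side(
            bundle.flows[flow_site], targets[f"{label}_mean_pressure"],
            targets.get(f"{label}_pulse_pressure",
                        0.45 * targets[f"{label}_mean_pressure"]),
            params.roots[root].r, params.roots[root].c,
            params.arterial_outlets(bed.split("_")[0]), p_out,
            tol, max_iter, report, label)
        params.beds[bed] = outlets
    if stage == 1:
        merged: dict = {}
        for _, e in report.history:
            merged.update(e)
        report.final_errors = merged
        report.converged = all(v < tol for v in merged.values())
        return params, report

    # ---- Stage 2: open-loop elastance hearts -------------------------
    p_fill = {"SA": 10.0, "MPA": 7.0}
    chamber_of = {"SA": "LV", "MPA": "RV"}
    for label, flow_site, bed, root, p_out in sides:
        if flow_site not in bundle.flows:
            continue
        q_t = targets.get(f"{flow_site}_mean_flow")
        p_t = targets.get(f"{label}_mean_pressure")
        if q_t is None or p_t is None:
            continue
        heart = params.chambers[chamber_of[label]]
        valve = params.valves["aortic" if label == "SA" else "pulmonary"]
        outlets = params.arterial_outlets(bed.split("_")[0])
        flow_meas = bundle.flows[flow_site]
        best = None
        for _ in range(8):
            sim = simulate_stage2(heart, valve, params.roots[root].r,
                                  params.roots[root].c, outlets, p_out,
                                  p_fill[label], period)
            errs = relative_errors(
                {f"{flow_site}_mean_flow": q_t, f"{label}_mean_pressure": p_t},
                {f"{flow_site}_mean_flow": sim["mean_flow"],
                 f"{label}_mean_pressure": sim["mean_pressure"]})
            report.history.append(({f"{label}_p_fill": p_fill[label]}, errs))
            report.iterations += 1
            best = sim
            if max(errs.values()) < tol:
                break
            p_fill[label] = update_initial_pressure(
                p_fill[label], q_t, sim["mean_flow"], p_t,
                sim["mean_pressure"])
        # ks from the ejection-waveform shape (L2 over one cycle)
        meas40 = np.asarray(flow_meas.values, dtype=float)
        best_ks, best_s = heart.ks, math.inf
        for ks_try in (0.0, 1e-4, 2e-4, 4e-4, 8e-4):
            heart.ks = ks_try
            sim = simulate_stage2(heart, valve, params.roots[root].r,
                                  params.roots[root].c, outlets, p_out,
                                  p_fill[label], period, max_cycles=8)
            sim40 = np.interp(np.arange(40) * period / 40.0, sim["time"],
                              sim["flow"])
            s_val = l2_discrepancy(meas40, sim40)
            if s_val < best_s:
                best_s, best_ks = s_val, ks_try
        heart.ks = best_ks
        report.notes.append(f"{label}: ks={best_ks} (L2={best_s:.1f})")
    if stage == 2:
        report.final_errors = dict(report.history[-1][1])
        report.converged = all(v < tol for v in report.final_errors.values())
        return params, report

    # ---- Stage 3: closed loop ----------------------------------------
    params.initial_pressures["pv"] = p_fill["SA"]
    params.initial_pressures["sv"] = p_fill["MPA"]
    keys3 = [k for k in ("MPA_mean_pressure", "MPA_sys_pressure",
                         "MPA_dias_pressure", "SA_mean_pressure",
                         "SA_sys_pressure", "SA_dias_pressure",
                         "AAo_mean_flow", "MPA_mean_flow") if k in targets]
    y0 = None
    damp = 1.0
    worse = 0
    prev_err = math.inf
    errs: dict = {}
    for it in range(max_iter):
        res = simulate(params, y0=y0, **sim_kwargs)
        y0 = res.y_final
        sim = _sim_metrics_for_targets(res)
        errs = relative_errors({k: targets[k] for k in keys3}, sim)
        report.history.append(
            ({"RT_sys": outlets_total_R(params.arterial_outlets("systemic")),
              "RT_pulm": outlets_total_R(params.arterial_outlets("pulmonary")),
              "CT_sys": outlets_total_C(params.arterial_outlets("systemic")),
              "CT_pulm": outlets_total_C(params.arterial_outlets("pulmonary"))},
             errs))
        report.iterations += 1
        err = max(errs.values())
        if err < tol:
            report.converged = True
            break
        if err > prev_err:
            worse += 1
            if worse >= 3:
                damp = 0.5
                report.notes.append(f"stage 3: damping engaged at iter {it}")
        else:
            worse = 0
        prev_err = err
        for label, flow_site, bed, root, p_out in sides:
            if f"{label}_mean_pressure" not in targets:
                continue
            side = bed.split("_")[0]
            outlets = params.arterial_outlets(side)
            rt = outlets_total_R(outlets)
            ct = outlets_total_C(outlets)
            q_sim = sim["AAo_mean_flow" if label == "SA" else "MPA_mean_flow"]
            rt_new = update_total_R(
                rt, targets[f"{label}_mean_pressure"],
                sim[f"{label}_mean_pressure"], q_sim)
            rt_new = max(rt_new, 0.05 * rt)
            pp_t = targets.get(f"{label}_pulse_pressure")
            ct_new = (update_total_C(ct, sim[f"{label}_pulse_pressure"], pp_t)
                      if pp_t else ct)
            params.beds[bed] = distribute_outlets(
                outlets, (rt_new / rt) ** damp, (ct_new / ct) ** damp)
        # Eq-7 style preload adjustment: venous initial pressures
        for label, ven in (("SA", "pv"), ("MPA", "sv")):
            q_key = "AAo_mean_flow" if label == "SA" else "MPA_mean_flow"
            if q_key in targets and f"{label}_mean_pressure" in targets:
                f = update_initial_pressure(
                    1.0, targets[q_key], sim[q_key],
                    targets[f"{label}_mean_pressure"],
                    sim[f"{label}_mean_pressure"]) ** damp
                params.initial_pressures[ven] = \
                    params.initial_pressures.get(ven, 8.0) * f
                y0 = None  # initial condition changed: restart transient
    report.final_errors = errs
    if not report.converged and report.max_error() > 2.0 * tol:
        report.notes.append("stage 3 did not converge; inspect history")
    return params, report


# ---------------------------------------------------------------------------
# Ventricular-model calibration (coordinate descent over Table-3 mapping)
# ---------------------------------------------------------------------------

VENTRICULAR_TARGET_KEYS = (
    "LV_EDV", "LV_ESV", "LV_ESP", "LV_EDP",
    "RV_EDV", "RV_ESV", "RV_ESP", "RV_EDP",
    "SA_mean_pressure", "SA_pulse_pressure",
    "MPA_mean_pressure", "MPA_pulse_pressure",
)


def _scale_two_hill(p, e_max=None, e_min=None):
    from .elastance import TwoHillParams
    return TwoHillParams(
        e_max=e_max if e_max is not None else p.e_max,
        e_min=e_min if e_min is not None else p.e_min,
        m1=p.m1, m2=p.m2, tau1=p.tau1, tau2=p.tau2, period=p.period)


def calibrate_ventricular(bundle_or_targets, tol: float = DEFAULT_TOL_PCT,
                          params0: CirculationParams = None,
                          max_sweeps: int = 50, damp: float = 0.7,
                          sim_kwargs: dict = None) -> tuple:
    """Closed-loop coordinate descent following the metric -> parameter
    mapping: venous resting volumes track EDV, arterial resistances track
    mean pressures (and ESV/ESP through afterload), compliances track
    pulse pressures, peak ventricular elastance tracks ESV, and diastolic
    elastance tracks EDP.  Each sweep simulates once and moves every
    mapped parameter by the damped target/simulated ratio.
    """
    if isinstance(bundle_or_targets, ClinicalBundle):
        targets = targets_from_bundle(bundle_or_targets)
    else:
        targets = dict(bundle_or_targets)
    targets = {k: v for k, v in targets.items()
               if k in VENTRICULAR_TARGET_KEYS and v is not None}
    for side in ("LV", "RV"):
        edv, esv = targets.get(f"{side}_EDV"), targets.get(f"{side}_ESV")
        if edv is not None and esv is not None and esv >= edv:
            raise ValueError(f"invalid targets: {side} ESV >= EDV")
    if not targets:
        raise ValueError("no usable ventricular targets")

    params = params0.copy() if params0 is not None else default_params()
    report = CalibrationReport()
    sim_defaults = {"periodicity_tol": 2e-3, "max_cycles": 15,
                    "min_cycles": 2, "n_out": 120}
    sim_defaults.update(sim_kwargs or {})
    y0 = None
    worse = 0
    prev_err = math.inf
    cur_damp = damp
    errs: dict = {}

    def clipped(r, lo=0.8, hi=1.25):
        return float(np.clip(r, lo, hi))

    for sweep in range(max_sweeps):
        res = simulate(params, y0=y0, **sim_defaults)
        y0 = res.y_final.copy()
        sim = _sim_metrics_for_targets(res)
        errs = relative_errors(targets, sim)
        report.history.append(({"vsv0": params.vsv0, "vpv0": params.vpv0},
                               errs))
        report.iterations += 1
        err = max(errs.values())
        if err < tol:
            report.converged = True
            break
        if err > prev_err:
            worse += 1
            if worse >= 3:
                cur_damp = 0.5 * damp
                report.notes.append(f"damping engaged at sweep {sweep}")
        else:
            worse = 0
        prev_err = err

        # venous resting volumes -> EDV; blood is added to (or removed
        # from) the corresponding venous compartment so the warm-started
        # state stays consistent with the new resting volume
        from .circulation import _Model
        idx = _Model(params).idx
        for key, attr, node in (("RV_EDV", "vsv0", "sv"),
                                ("LV_EDV", "vpv0", "pv")):
            if key in targets:
                delta = cur_damp * 2.0 * (targets[key] - sim[key])
                delta = float(np.clip(delta, -60.0, 60.0))
                setattr(params, attr, max(getattr(params, attr) + delta, 1.0))
                y0[idx[node]] = max(y0[idx[node]] + delta, 1.0)
        # arterial resistances -> mean pressures
        for key, side in (("SA_mean_pressure", "systemic"),
                          ("MPA_mean_pressure", "pulmonary")):
            if key in targets:
                r = clipped((targets[key] / sim[key]) ** cur_damp)
                params.beds[f"{side}_art"] = distribute_outlets(
                    params.arterial_outlets(side), r, 1.0)
        # compliances -> pulse pressures (stable orientation)
        for key, side, root in (("SA_pulse_pressure", "systemic", "aortic"),
                                ("MPA_pulse_pressure", "pulmonary", "pulmonary")):
            if key in targets:
                r = clipped((sim[key] / targets[key]) ** cur_damp)
                params.beds[f"{side}_art"] = distribute_outlets(
                    params.arterial_outlets(side), 1.0, r)
                params.roots[root].c *= r
        # contractility -> ESV; diastolic stiffness -> EDP
        for side in ("LV", "RV"):
            ch = params.chambers[side]
            el = ch.elastance
            if f"{side}_ESV" in targets:
                r = clipped((max(sim[f"{side}_ESV"] - ch.v0, 1.0)
                             / max(targets[f"{side}_ESV"] - ch.v0, 1.0))
                            ** cur_damp)
                new_emax = float(np.clip(el.e_max * r, 8.0 * el.e_min, 20.0))
                ch.elastance = _scale_two_hill(el, e_max=new_emax)
            el = ch.elastance
            if f"{side}_EDP" in targets and sim[f"{side}_EDP"] > 0:
                r = clipped((targets[f"{side}_EDP"] / sim[f"{side}_EDP"])
                            ** cur_damp, 0.85, 1.2)
                new_emin = float(np.clip(el.e_min * r, 1e-3, 0.25 * el.e_max))
                ch.elastance = _scale_two_hill(el, e_min=new_emin)
    report.final_errors = errs
    return params, report
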