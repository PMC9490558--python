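"""Ventricular elastance: clinical series, the analytic two-Hill waveform,
volume-waveform adjustment from phase-contrast MRI, and the L2 discrepancy
metric used to compare measured and simulated waveforms.

The two-Hill elastance is the product of an ascending and a descending
Hill sigmoid,

    E(t) = k * g1/(1+g1) * 1/(1+g2) + Emin,
    g1 = (t/tau1)^m1,  g2 = (t/tau2)^m2,

with k chosen so the maximum over one cycle equals Emax - Emin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .datamodel import Waveform
from .pv_alignment import PVLoop


@dataclass(frozen=True)
class TwoHillParams:
    e_max: float   # mmHg/ml
    e_min: float   # mmHg/ml
    m1: float      # ascending slope exponent
    m2: float      # descending slope exponent
    tau1: float    # s, ascending time scale
    tau2: float    # s, descending time scale
    period: float  # s

    def __post_init__(self) -> None:
        if not (self.e_max > self.e_min > 0):
            raise ValueError("need e_max > e_min > 0")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("Hill exponents must be positive")
        if not (0 < self.tau1 < self.period and 0 < self.tau2 < self.period):
            raise ValueError("time scales must lie in (0, period)")


@dataclass
class ElastanceSeries:
    e_i: np.ndarray    # mmHg/ml
    times: np.ndarray  # s

    def __post_init__(self) -> None:
        self.e_i = np.asarray(self.e_i, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.e_i <= 0):
            raise ValueError("elastance values must be positive")


def _hill_shape(t, m1, m2, tau1, tau2):
    """Unscaled two-Hill product g1/(1+g1) * 1/(1+g2)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        g1 = (t / tau1) ** m1
        g2 = (t / tau2) ** m2
        out = (g1 / (1.0 + g1)) * (1.0 / (1.0 + g2))
    return np.where(t <= 0.0, 0.0, out)


def _hill_shape_max(m1, m2, tau1, tau2, period) -> float:
    """Maximum of the unscaled product over one cycle (grid + refinement)."""
    tt = np.linspace(0.0, period, 2049)
    vals = _hill_shape(tt, m1, m2, tau1, tau2)
    i = int(np.argmax(vals))
    lo = tt[max(i - 1, 0)]
    hi = tt[min(i + 1, len(tt) - 1)]
    res = minimize_scalar(
        lambda t: -_hill_shape(t, m1, m2, tau1, tau2),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(max(vals[i], -res.fun))


def two_hill_scale(params: TwoHillParams) -> float:
    """The scale factor k = (Emax - Emin)/max over the cycle of the product."""
    peak = _hill_shape_max(params.m1, params.m2, params.tau1, params.tau2,
                           params.period)
    return (params.e_max - params.e_min) / peak


def two_hill(t, params: TwoHillParams):
    """Two-Hill elastance at time ``t`` (s, within one cycle; scalar or array)."""
    k = two_hill_scale(params)
    return k * _hill_shape(np.mod(t, params.period), params.m1, params.m2,
                           params.tau1, params.tau2) + params.e_min


def elastance_series(loop: PVLoop, v0: float = 0.0) -> ElastanceSeries:
    """Clinical elastance E_i = P_i / (V_i - v0) from an aligned PV loop.

    The default v0 = 0 matches the clinical definition E_i = P_i/V_i; a
    nonzero unloaded volume can be supplied when known.
    """
    v = loop.volume - v0
    if np.any(v <= 0):
        raise ValueError("volumes must exceed the unloaded volume everywhere")
    n = len(v)
    times = np.arange(n) * loop.period / n
    return ElastanceSeries(loop.pressure / v, times)


_FIT_STARTS = [
    # (m1, m2, tau1/T, tau2/T) multi-start grid
    (1.32, 27.4, 0.269, 0.452),
    (2.0, 10.0, 0.2, 0.4),
    (1.0, 20.0, 0.3, 0.5),
    (3.0, 40.0, 0.25, 0.45),
    (1.5, 15.0, 0.35, 0.55),
]


def fit_two_hill(series: ElastanceSeries, period: float) -> tuple:
    """Fit two-Hill parameters to a clinical elastance series.

    Bounded nonlinear least squares over (e_max, e_min, m1, m2, tau1,
    dtau = tau2 - tau1 > 0) from a fixed multi-start grid; returns
    ``(TwoHillParams, rmse)`` for the best start.  A near-constant series
    yields a degenerate fit (e_max ~ e_min) with a warning.
    """
    e = np.asarray(series.e_i, dtype=float)
    t = np.asarray(series.times, dtype=float)
    if len(e) < 10:
        raise ValueError("need at least 10 elastance samples")
    e_hi, e_lo = float(np.max(e)), float(np.min(e))
    if e_hi - e_lo < 1e-9 * max(e_hi, 1.0):
        warnings.warn("constant elastance series: degenerate two-Hill fit")
        p = TwoHillParams(e_hi + 1e-9, max(e_lo, 1e-12), 1.0, 20.0,
                          0.3 * period, 0.45 * period, period)
        return p, float(np.sqrt(np.mean((e - e_hi) ** 2)))

    def unpack(x):
        e_max, e_min, m1, m2, tau1, dtau = x
        return TwoHillParams(e_max, e_min, m1, m2, tau1,
                             min(tau1 + dtau, 0.999 * period), period)

    def resid(x):
        try:
            return two_hill(t, unpack(x)) - e
        except ValueError:
            return np.full_like(e, 1e6)

    lb = [e_lo, 1e-8, 0.2, 0.2, 1e-3 * period, 1e-3 * period]
    ub = [10.0 * e_hi, e_hi, 80.0, 80.0, 0.95 * period, 0.95 * period]
    best = None
    for m1, m2, f1, f2 in _FIT_STARTS:
        x0 = [e_hi, max(e_lo, 1e-6), m1, m2, f1 * period,
              max((f2 - f1) * period, 1e-3 * period)]
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14,
                                ftol=1e-14, gtol=1e-14, max_nfev=4000)
        except Exception:
            continue
        rmse = float(np.sqrt(np.mean(sol.fun ** 2)))
        key = (rmse, sol.x[3])  # tie-break: lowest RMSE, then lowest m2
        if best is None or key < best[0]:
            best = (key, sol.x)
    if best is None:
        raise RuntimeError("two-Hill fit failed from every start")
    params = unpack(best[1])
    return params, best[0][0]


def _systole_window(flow: Waveform, threshold_frac: float = 0.05):
    """Contiguous phase run around peak flow where flow > threshold_frac*peak."""
    v = flow.values
    n = len(v)
    peak = int(np.argmax(v))
    thr = threshold_frac * v[peak]
    lo = peak
    while v[(lo - 1) % n] > thr and (peak - lo) < n - 1:
        lo -= 1
    hi = peak
    while v[(hi + 1) % n] > thr and (hi - peak) < n - 1:
        hi += 1
    return lo, hi  # inclusive indices, possibly negative (periodic)


def adjust_volume_waveform(cine_vol: Waveform, pc_flow: Waveform,
                           threshold_frac: float = 0.05) -> Waveform:
    """Rebuild the systolic limb of a cine-MRI ventricular volume waveform
    from the PC-MRI outflow waveform.

    Breath-held cine MRI inflates stroke volume relative to free-breathing
    PC-MRI, and cine systole is too short; the flow integral has the right
    shape.  The ejection segment becomes EDV - s * cumulative flow integral
    with s = SV_cine / SV_pcmri, so the output keeps the cine EDV and SV
    exactly while following the PC-MRI ejection time course.  The filling
    (diastolic) limb is the cine waveform, resampled onto the remaining
    phases.  Output is a 30-phase waveform starting at end-diastole.
    """
    n = cine_vol.n_phases
    period = cine_vol.period
    # Roll the cine waveform so phase 0 is end-diastole.
    i_ed = int(np.argmax(cine_vol.values))
    cine = np.roll(cine_vol.values, -i_ed)
    edv = float(cine[0])
    esv = float(np.min(cine))
    sv_cine = edv - esv
    i_es = int(np.argmin(cine))
    t_es_cine = i_es * period / n

    lo, hi = _systole_window(pc_flow, threshold_frac)
    nf = pc_flow.n_phases
    dtf = pc_flow.period / nf
    # include the sub-threshold edge samples so the window starts at the
    # true flow onset and the integral captures the full ejected volume
    idx = np.arange(lo - 1, hi + 2)
    tf = idx * dtf
    f = pc_flow.values[idx % nf]
    cum = np.concatenate(([0.0], np.cumsum((f[1:] + f[:-1]) / 2.0 * dtf)))
    sv_pc = float(cum[-1])
    if sv_pc <= 0:
        raise ValueError("PC-MRI stroke volume must be positive")
    dur_raw = min(float(tf[-1] - tf[0]), 0.9 * period)
    # snap the ejection window down to the output grid and scale the flow
    # integral so the sample AT the window end reads exactly ESV: stroke
    # volume is then conserved by construction, and when the flow already
    # matches the cine systole the whole waveform is reproduced
    step = period / n
    k_sys = max(int(dur_raw / step), 1)
    dur_sys = k_sys * step
    f_end = float(np.interp(dur_sys, tf - tf[0], cum))
    s = sv_cine / f_end

    t_out = np.arange(n) * period / n
    out = np.empty(n)
    in_sys = t_out <= dur_sys + 1e-12
    out[in_sys] = edv - s * np.interp(t_out[in_sys], tf - tf[0], cum)
    # Diastolic limb: map [dur_sys, period] onto the cine filling segment.
    td = t_out[~in_sys]
    denom = period - dur_sys
    mapped = t_es_cine + (td - dur_sys) / denom * (period - t_es_cine)
    out[~in_sys] = Waveform(cine, period).sample(mapped)
    # SV is conserved by construction: out[0] = EDV and the ejection limb
    # ends at EDV - s*SV_pc = ESV_cine, where the cine filling limb resumes.
    return Waveform(out, period)


def l2_discrepancy(data, sim) -> float:
    """Sum of squared differences between a measured and simulated signal."""
    data = np.asarray(data, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if data.shape != sim.shape:
        raise ValueError("arrays must have equal length")
    return float(np.sum((data - sim) ** 2))
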