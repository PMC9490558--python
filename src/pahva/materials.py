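"""Myocardial constitutive laws and ventricular-arterial coupling metrics.

Active contraction is a time-varying elastance-type law along the local
fiber direction with length-dependent calcium sensitivity; the passive
response is a transversely isotropic Fung-type exponential strain-energy
function in fiber/sheet/sheet-normal coordinates.  The laws are exercised
exactly at material points; organ-level mechanics are reduced to a
thick-walled-sphere equilibrium driver (a deliberately simple surrogate
for full 3D biventricular FEM -- see the methods note).

The end-systolic pressure-volume relationship (ESPVR), arterial elastance
Ea = P_es/SV, and the coupling ratio ESPVR/Ea are derived by virtual
preload variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .circulation import CirculationParams, simulate, _Model
from .elastance import TwoHillParams
from .units import KPA_TO_MMHG


@dataclass
class ActiveParams:
    """Active contraction constants.

    t_ref: reference tension (kPa); ca0 / ca0_max: peak and maximum peak
    intracellular calcium (arbitrary units); b_len: length sensitivity
    (1/um); l0: sarcomere length below which no tension develops (um);
    t0: time of peak tension (s); tt: start of relaxation (s); tau:
    relaxation time constant (s).
    """

    t_ref: float = 80.0
    ca0: float = 4.35
    ca0_max: float = 4.35
    b_len: float = 4.75
    l0: float = 1.58
    t0: float = 0.25
    tt: float = 0.35
    tau: float = 0.03

    def __post_init__(self) -> None:
        if self.t_ref <= 0 or self.tau <= 0 or self.l0 <= 0:
            raise ValueError("t_ref, tau and l0 must be positive")


@dataclass
class PassiveParams:
    """Fung-type transversely isotropic constants: W = c/2 (e^Q - 1).

    Default exponents are illustrative mid-range myocardium values.
    """

    c_scale: float = 0.2   # kPa
    b_ff: float = 29.9
    b_xx: float = 13.3
    b_fx: float = 26.6

    def __post_init__(self) -> None:
        if min(self.c_scale, self.b_ff, self.b_xx, self.b_fx) <= 0:
            raise ValueError("all passive constants must be positive")


@dataclass
class MaterialState:
    """Green-Lagrange strain in the (f, s, n) material frame plus fiber
    directions and sarcomere length."""

    strain_E: np.ndarray
    fiber_dir_ref: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    fiber_dir_cur: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    sarc_len: float = 1.85

    def __post_init__(self) -> None:
        self.strain_E = np.asarray(self.strain_E, dtype=float)
        if self.strain_E.shape != (3, 3):
            raise ValueError("strain must be 3x3")
        if not np.allclose(self.strain_E, self.strain_E.T, atol=1e-10):
            raise ValueError("strain must be symmetric")
        for v in (self.fiber_dir_ref, self.fiber_dir_cur):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError("fiber directions must be unit vectors")


def active_ct(t: float, params: ActiveParams) -> float:
    """Activation time course C(t): raised-cosine rise to peak tension at
    t0, frozen at its value when relaxation starts at tt, then exponential
    decay with constant tau."""
    if params.t0 <= 0:
        raise ValueError("t0 must be positive")
    if t < 0:
        return 0.0
    if t < params.tt:
        return 0.5 * (1.0 - math.cos(math.pi * t / params.t0))
    peak = 0.5 * (1.0 - math.cos(math.pi * params.tt / params.t0))
    return peak * math.exp(-(t - params.tt) / params.tau)


def eca50(l: float, params: ActiveParams, printed_form: bool = False) -> float:
    """Length-dependent calcium sensitivity.

    Standard form (default): ECa50 = Ca0_max / sqrt(exp(B (l - l0)) - 1),
    positive and decreasing in sarcomere length l; undefined (no tension
    regime) for l <= l0.  ``printed_form`` selects the literal variant
    Ca0_max / sqrt(exp(B (l - l0) - 1)) for comparison.
    """
    x = params.b_len * (l - params.l0)
    if printed_form:
        return params.ca0_max / math.sqrt(math.exp(x - 1.0))
    if x <= 0:
        raise ValueError("sarcomere length at or below zero-tension length")
    return params.ca0_max / math.sqrt(math.expm1(x))


def active_tension(l: float, t: float, params: ActiveParams) -> float:
    """Scalar active fiber tension (kPa) at sarcomere length l and time t."""
    if l <= params.l0:
        return 0.0
    e50 = eca50(l, params)
    return (params.t_ref * params.ca0 ** 2 / (params.ca0 ** 2 + e50 ** 2)
            * active_ct(t, params))


def active_stress(state: MaterialState, params: ActiveParams,
                  t: float) -> np.ndarray:
    """Active stress tensor (kPa): scalar tension times e_f (x) e_f0."""
    mag = active_tension(state.sarc_len, t, params)
    return mag * np.outer(state.fiber_dir_cur, state.fiber_dir_ref)


_B_WEIGHTS_CACHE = {}


def _b_weights(params: PassiveParams) -> np.ndarray:
    key = (params.b_ff, params.b_xx, params.b_fx)
    if key not in _B_WEIGHTS_CACHE:
        b = np.array([
            [params.b_ff, params.b_fx, params.b_fx],
            [params.b_fx, params.b_xx, params.b_xx],
            [params.b_fx, params.b_xx, params.b_xx],
        ])
        _B_WEIGHTS_CACHE[key] = b
    return _B_WEIGHTS_CACHE[key]


def strain_energy(state: MaterialState, params: PassiveParams) -> float:
    """Fung-type strain energy W = c/2 (e^Q - 1) with
    Q = b_ff E_ff^2 + b_xx (E_ss^2 + E_nn^2 + E_sn^2 + E_ns^2)
      + b_fx (E_fn^2 + E_nf^2 + E_fs^2 + E_sf^2)."""
    E = state.strain_E
    Q = float(np.sum(_b_weights(params) * E * E))
    return 0.5 * params.c_scale * math.expm1(Q)


def passive_stress(state: MaterialState, params: PassiveParams) -> np.ndarray:
    """Second Piola-Kirchhoff passive stress S = dW/dE (kPa):
    S_ij = c e^Q b_ij E_ij componentwise in the material frame."""
    E = state.strain_E
    b = _b_weights(params)
    Q = float(np.sum(b * E * E))
    return params.c_scale * math.exp(Q) * b * E


@dataclass
class SphereVentricle:
    """Thick-walled incompressible spherical ventricle at the midwall.

    Cavity pressure follows Laplace equilibrium P = 2 sigma h / r with the
    total (active + passive) circumferential fiber stress evaluated at the
    midwall stretch; sarcomere length maps linearly from the
    circumferential stretch, l = l_ref * lambda.
    """

    cavity_v: float            # ml
    wall_v: float              # ml, constant (incompressible wall)
    active: ActiveParams = field(default_factory=ActiveParams)
    passive: PassiveParams = field(default_factory=PassiveParams)
    ref_cavity_v: float = 40.0  # ml, unloaded cavity volume
    l_ref: float = 1.85         # um at lambda = 1

    def __post_init__(self) -> None:
        if self.wall_v <= 0 or self.ref_cavity_v <= 0:
            raise ValueError("wall and reference volumes must be positive")

    def _geometry(self, v: float):
        r_i = (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
        r_o = (3.0 * (v + self.wall_v) / (4.0 * math.pi)) ** (1.0 / 3.0)
        return 0.5 * (r_i + r_o), r_o - r_i  # midwall radius, thickness


def sphere_pv(ventricle: SphereVentricle, t: float,
              activation: bool = True,
              cavity_v: float = None) -> float:
    """Cavity pressure (mmHg) of the sphere ventricle at time t.

    Midwall circumferential stretch lambda = r_m/r_m_ref; equibiaxial
    in-plane Green strain E = (lambda^2 - 1)/2 with radial strain from
    incompressibility; total stress = passive S_ff + active tension.
    """
    v = ventricle.cavity_v if cavity_v is None else cavity_v
    if v <= 0:
        raise ValueError("cavity volume must be positive")
    r_m, h = ventricle._geometry(v)
    r_ref, _ = ventricle._geometry(ventricle.ref_cavity_v)
    lam = r_m / r_ref
    e_cc = 0.5 * (lam * lam - 1.0)
    e_rr = 0.5 * (lam ** -4 - 1.0)
    E = np.diag([e_cc, e_cc, e_rr])
    state = MaterialState(strain_E=E, sarc_len=ventricle.l_ref * lam)
    sigma = passive_stress(state, ventricle.passive)[0, 0]
    if activation:
        sigma += active_tension(state.sarc_len, t, ventricle.active)
    return float(sigma * KPA_TO_MMHG * 2.0 * h / r_m)


@dataclass
class SphereAfterload:
    """Preload reservoir + 3-element Windkessel afterload for the isolated
    sphere-ventricle driver."""

    p_preload: float = 10.0   # mmHg
    r_in: float = 0.01        # mmHg*s/ml, filling resistance
    r_prox: float = 0.03
    c: float = 1.5
    r_dist: float = 1.0
    p_out: float = 5.0        # mmHg, downstream reference


def sphere_loop(ventricle: SphereVentricle, load: SphereAfterload,
                period: float = 0.8, max_cycles: int = 30,
                tol: float = 1e-3) -> dict:
    """Periodic PV loop of the isolated sphere ventricle.

    States: cavity volume and Windkessel pressure; smooth diode valves.
    Returns time, volume, pressure arrays of the last cycle plus the
    end-systolic point taken at the start of relaxation (peak activation).
    """

    def diode(dp, r, w=1e-3):
        return 0.5 * (dp + np.sqrt(dp * dp + w * w)) / r

    def rhs(t, y):
        v, pc = y
        # floor guards trial steps; strong suction (negative passive
        # stress below the reference volume) restores the volume
        p_v = sphere_pv(ventricle, t % period, cavity_v=max(v, 1e-3))
        q_in = diode(load.p_preload - p_v, load.r_in)
        q_out = diode(p_v - pc, load.r_prox)
        dpc = (q_out - (pc - load.p_out) / load.r_dist) / load.c
        return [q_in - q_out, dpc]

    y = [ventricle.ref_cavity_v * 1.2, load.p_preload]
    prev = None
    for k in range(max_cycles):
        tt = np.linspace(k * period, (k + 1) * period, 201)
        sol = solve_ivp(rhs, (k * period, (k + 1) * period), y,
                        method="LSODA", t_eval=tt, rtol=1e-7, atol=1e-9)
        y = sol.y[:, -1]
        sv = float(np.max(sol.y[0]) - np.min(sol.y[0]))
        if prev is not None and abs(sv - prev) < tol * max(prev, 1.0):
            break
        prev = sv
    t_loc = sol.t - sol.t[0]
    p = np.array([sphere_pv(ventricle, ti, cavity_v=vi)
                  for ti, vi in zip(t_loc, sol.y[0])])
    i_es = int(np.argmin(np.abs(t_loc - min(ventricle.active.tt,
                                            ventricle.active.t0))))
    return {"time": t_loc, "volume": sol.y[0], "pressure": p,
            "v_es": float(sol.y[0][i_es]), "p_es": float(p[i_es]),
            "sv": float(np.max(sol.y[0]) - np.min(sol.y[0]))}


def espvr(params: CirculationParams, vsv0_grid, chamber: str = "RV",
          sim_kwargs: dict = None) -> dict:
    """ESPVR by virtual preload variation in the closed loop.

    For each venous resting volume in ``vsv0_grid`` (systemic for the RV,
    pulmonary for the LV) the loop is simulated to periodicity and the
    end-systolic point is taken at the instant of peak ventricular
    elastance in the last cycle.  Returns the linear-regression slope
    (mmHg/ml), intercept, and the (V_es, P_es) points.
    """
    sim_kwargs = dict(sim_kwargs or {})
    points = []
    y0 = None
    for v_rest in vsv0_grid:
        p = params.copy()
        if chamber == "RV":
            p.vsv0 = float(v_rest)
        else:
            p.vpv0 = float(v_rest)
        res = simulate(p, y0=y0, **sim_kwargs)
        if not res.converged:
            raise RuntimeError(f"preload {v_rest}: simulation not periodic")
        y0 = res.y_final
        lc = res.last_cycle()
        model = _Model(p)
        e_tab = model.tabs[chamber]
        tgrid = np.linspace(0.0, p.period, len(e_tab))
        e_t = np.interp(np.mod(lc.time, p.period), tgrid, e_tab)
        i_es = int(np.argmax(e_t))
        points.append((float(lc.volumes[chamber][i_es]),
                       float(lc.pressures[chamber][i_es])))
    if len(points) < 3:
        raise ValueError("need at least 3 preload values")
    v, pp = np.array(points).T
    slope, intercept = np.polyfit(v, pp, 1)
    return {"slope": float(slope), "intercept": float(intercept),
            "points": points}


def arterial_elastance(p_es: float, sv: float) -> float:
    """Arterial elastance Ea = end-systolic pressure / stroke volume."""
    if sv <= 0:
        raise ValueError("stroke volume must be positive")
    return p_es / sv


def coupling(espvr_slope: float, ea: float) -> float:
    """Ventricular-arterial coupling ratio ESPVR/Ea."""
    if ea <= 0:
        raise ValueError("Ea must be positive")
    return espvr_slope / ea
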