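"""Arterial wall mechanics at the five measurement sites (AAo, DTA, MPA,
LPA, RPA): linearized stiffness from radius and pulse-pressure excursions,
Moens-Korteweg wave speed, path-aggregated pulse wave velocity, and the
central/peripheral resistance-compliance split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .units import BLOOD_DENSITY_G_MM3, MMHG_TO_KPA

WALL_THICKNESS_RATIO = 0.15  # wall thickness / diastolic luminal radius

SITE_NAMES = ("AAo", "DTA", "MPA", "LPA", "RPA")


@dataclass
class VesselSite:
    """Per-site radius and pressure excursions (radii mm, pressures mmHg)."""

    name: str
    r_dias: float
    r_sys: float
    p_sys: float
    p_dias: float

    def __post_init__(self) -> None:
        if not (self.r_sys > self.r_dias > 0):
            raise ValueError("need r_sys > r_dias > 0")
        if not self.p_sys > self.p_dias:
            raise ValueError("need p_sys > p_dias")

    @classmethod
    def from_areas(cls, name, a_dias_mm2, a_sys_mm2, p_sys, p_dias):
        """Radii from PC-MRI luminal areas assuming a circular lumen."""
        return cls(name, math.sqrt(a_dias_mm2 / math.pi),
                   math.sqrt(a_sys_mm2 / math.pi), p_sys, p_dias)


@dataclass
class VesselSegment:
    site: VesselSite
    stiffness_E: float   # kPa
    length: float = 10.0  # mm
    wall_h: float = field(default=None)  # mm
    blood_density: float = BLOOD_DENSITY_G_MM3 * 1e6  # kg/m^3

    def __post_init__(self) -> None:
        if self.wall_h is None:
            self.wall_h = WALL_THICKNESS_RATIO * self.site.r_dias
        if self.stiffness_E <= 0:
            raise ValueError("stiffness must be positive")


def linearized_stiffness(site: VesselSite) -> float:
    """Linearized arterial stiffness in kPa,

        E = 1.5 * dP * Ri^2 * Ro / ((Ro^2 - Ri^2) * dR),

    with Ri the diastolic luminal radius, Ro = Ri * 1.15 the outer radius
    (15% wall-thickness rule), dR the systolic-diastolic radius excursion
    and dP the pulse pressure (converted to kPa before evaluation).
    """
    ri = site.r_dias
    ro = ri * (1.0 + WALL_THICKNESS_RATIO)
    dr = site.r_sys - site.r_dias
    if dr <= 0:
        raise ValueError("non-distensible measurement: dR <= 0")
    dp_kpa = (site.p_sys - site.p_dias) * MMHG_TO_KPA
    return 1.5 * dp_kpa * ri * ri * ro / ((ro * ro - ri * ri) * dr)


def moens_korteweg_pwv(segment: VesselSegment) -> float:
    """Moens-Korteweg wave speed c = sqrt(E*h / (2*rho*Ri)) in m/s.

    This is a material wave-speed surrogate for the pulse wave velocity of
    a segment; E in kPa, h and Ri in mm, rho in kg/m^3.
    """
    e_pa = segment.stiffness_E * 1e3
    h_m = segment.wall_h * 1e-3
    ri_m = segment.site.r_dias * 1e-3
    return math.sqrt(e_pa * h_m / (2.0 * segment.blood_density * ri_m))


def path_pwv(segments: Sequence[VesselSegment],
             method: str = "harmonic_transit") -> float:
    """Pulse wave velocity along an ordered arterial path: total length
    divided by total transit time (per-segment time = length / c)."""
    if method != "harmonic_transit":
        raise ValueError(f"unknown method {method!r}")
    if not segments:
        raise ValueError("need at least one segment")
    total_len = sum(s.length for s in segments)
    transit = sum(s.length / moens_korteweg_pwv(s) for s in segments)
    return total_len / transit


def central_peripheral_split(central_r: float, central_c: float,
                             windkessels) -> tuple:
    """Fraction of total resistance and compliance held by the central
    (image-resolved) arteries versus the peripheral Windkessel beds.

    Peripheral resistances combine in parallel, compliances add.  Each
    Windkessel contributes r_prox + r_dist in series and its compliance c.
    """
    if central_r < 0 or central_c < 0:
        raise ValueError("central parameters must be non-negative")
    if not windkessels:
        raise ValueError("need at least one peripheral Windkessel")
    inv_r = 0.0
    c_sum = 0.0
    for wk in windkessels:
        if isinstance(wk, (tuple, list)):
            r, c = wk
        else:
            r = wk.r_prox + wk.r_dist
            c = wk.c
        if r <= 0 or c <= 0:
            raise ValueError("peripheral parameters must be positive")
        inv_r += 1.0 / r
        c_sum += c
    r_periph = 1.0 / inv_r
    frac_r = central_r / (central_r + r_periph)
    frac_c = central_c / (central_c + c_sum)
    return frac_r, frac_c
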