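"""Pressure-volume loop alignment.

Catheter pressure and MRI volume waveforms are acquired on different days
and clocks, so an ECG-aligned PV loop often lacks the isovolumetric
segments a physiological loop must show.  This module restores alignment
by cyclically shifting the 30-phase pressure waveform over +/-7 phase
increments and keeping the shift whose 30 (V, P) points are best fit by
the largest-area ellipse (direct least-squares conic fit constrained to an
ellipse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Waveform
from .units import MMHG_ML_TO_J

MAX_SHIFT = 7


class DegenerateEllipseError(ValueError):
    """Raised when the conic fit does not yield a real ellipse."""


@dataclass
class ConicEllipse:
    center: tuple        # (V, P)
    semi_axes: tuple     # (a, b) with a >= b > 0
    angle: float         # radians, major-axis orientation
    area: float          # pi*a*b, mmHg*ml

    def points(self, n: int = 100, phase: float = 0.0) -> np.ndarray:
        """Sample n points on the ellipse (parametric, for synthesis/tests)."""
        th = 2.0 * np.pi * np.arange(n) / n + phase
        a, b = self.semi_axes
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        x = a * np.cos(th)
        y = b * np.sin(th)
        return np.column_stack(
            (self.center[0] + ca * x - sa * y, self.center[1] + sa * x + ca * y)
        )


@dataclass
class PVLoop:
    pressure: np.ndarray   # mmHg
    volume: np.ndarray     # ml
    period: float          # s

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if len(self.pressure) != len(self.volume):
            raise ValueError("pressure and volume arrays must have equal length")


@dataclass
class AlignmentResult:
    n_star: int
    loop: PVLoop
    ellipse_area: float
    areas_by_shift: dict


def downsample_pressure(pressure: Waveform, n: int = 30) -> np.ndarray:
    """Down-sample a catheter pressure waveform to ``n`` phases at times
    k/n * T by periodic linear interpolation."""
    if n < 8:
        raise ValueError("cannot downsample below 8 phases")
    return pressure.resample(n).values


def cyclic_shift(values, n_shift: int):
    """Cyclic shift: result[i] = values[(i - n_shift) mod n].

    A positive ``n_shift`` moves the signal later in the cycle.
    """
    return np.roll(np.asarray(values), n_shift)


def fit_ellipse(points) -> ConicEllipse:
    """Direct least-squares ellipse fit (Fitzgibbon-type, in the
    numerically stable partitioned form) returning geometric parameters.

    Requires at least 5 non-collinear points; raises
    :class:`DegenerateEllipseError` otherwise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise DegenerateEllipseError("need at least 5 (V, P) points")
    mean = pts.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum((pts - mean) ** 2, axis=1))))
    if scale <= 0:
        raise DegenerateEllipseError("all points coincide")
    x, y = ((pts - mean) / scale).T

    # Partitioned (Halir-Flusser) solution of the constrained conic fit.
    D1 = np.column_stack((x * x, x * y, y * y))
    D2 = np.column_stack((x, y, np.ones_like(x)))
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as err:
        raise DegenerateEllipseError("degenerate point configuration") from err
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.where(np.isreal(eigval) & (cond > 0))[0]
    if len(ok) == 0:
        raise DegenerateEllipseError("constrained fit yields no ellipse")
    a1 = np.real(eigvec[:, ok[0]])
    coeffs = np.concatenate((a1, T @ a1))
    A, B, C, D, E, F = coeffs

    disc = B * B - 4.0 * A * C
    if disc >= 0:
        raise DegenerateEllipseError("fitted conic is not an ellipse")
    x0 = (2.0 * C * D - B * E) / disc
    y0 = (2.0 * A * E - B * D) / disc
    fc = F + (D * x0 + E * y0) / 2.0
    Amat = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam = np.linalg.eigvalsh(Amat)
    with np.errstate(invalid="ignore", divide="ignore"):
        ax2 = -fc / lam
    if np.any(ax2 <= 0) or not np.all(np.isfinite(ax2)):
        raise DegenerateEllipseError("fitted conic is degenerate")
    axes = np.sqrt(ax2)
    semi_major, semi_minor = float(max(axes)) * scale, float(min(axes)) * scale
    # Orientation of the major axis: eigenvector of the smaller |lambda|.
    idx = int(np.argmax(ax2))
    vec = np.linalg.eigh(Amat)[1][:, idx]
    angle = float(np.arctan2(vec[1], vec[0])) % np.pi
    return ConicEllipse(
        center=(float(mean[0] + scale * x0), float(mean[1] + scale * y0)),
        semi_axes=(semi_major, semi_minor),
        angle=angle,
        area=float(np.pi * semi_major * semi_minor),
    )


def align_pv_loop(pressure, volume, period: float,
                  max_shift: int = MAX_SHIFT) -> AlignmentResult:
    """Find the pressure shift in [-max_shift, +max_shift] phase increments
    whose (V, shifted P) points admit the largest-area ellipse fit.

    Ties within 1e-9 relative area are broken toward the smallest |shift|
    (maximum pressure and minimum volume should stay in close temporal
    proximity).
    """
    pressure = np.asarray(pressure, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if len(pressure) != len(volume):
        raise ValueError("pressure and volume must have equal length")
    areas: dict = {}
    for n in range(-max_shift, max_shift + 1):
        shifted = cyclic_shift(pressure, n)
        try:
            areas[n] = fit_ellipse(np.column_stack((volume, shifted))).area
        except DegenerateEllipseError:
            areas[n] = float("nan")
    valid = {n: a for n, a in areas.items() if np.isfinite(a)}
    if not valid:
        raise DegenerateEllipseError("ellipse fit degenerate at every shift")
    best_area = max(valid.values())
    # smallest |n| among near-ties, then smallest n for full determinism
    candidates = [n for n, a in valid.items()
                  if a >= best_area * (1.0 - 1e-9)]
    n_star = min(candidates, key=lambda n: (abs(n), n))
    loop = PVLoop(cyclic_shift(pressure, n_star), volume, period)
    return AlignmentResult(n_star=n_star, loop=loop,
                           ellipse_area=valid[n_star], areas_by_shift=areas)


def stroke_work(loop: PVLoop) -> float:
    """Ventricular stroke work in joules: absolute shoelace area of the
    closed P-V contour converted from mmHg*ml."""
    v, p = loop.volume, loop.pressure
    area = 0.5 * np.abs(np.dot(v, np.roll(p, -1)) - np.dot(p, np.roll(v, -1)))
    return float(area * MMHG_ML_TO_J)
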