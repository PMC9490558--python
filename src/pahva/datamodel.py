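"""Core domain types and I/O: patient records, periodic waveforms, clinical
bundles, the embedded eight-subject cohort, and derived scalar metrics.

Unit conventions are package-wide (see :mod:`pahva.units`): pressures mmHg,
volumes ml, flows ml/s, time s.  Scalar metrics keep their clinical
reporting units (flows in L/min, PVRi in WU*m^2, EF in %).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from . import cohort_data


class WaveformFormatError(ValueError):
    """Raised when a waveform file violates the two-column uniform-grid contract."""


@dataclass
class Waveform:
    """Uniformly sampled periodic signal over one cardiac cycle.

    ``values[k]`` is the sample at time ``k * period / n_phases``; index
    arithmetic is modular, so the signal is treated as periodic.
    """

    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("waveform values must be a 1-D array")
        if self.n_phases < 8:
            raise ValueError(f"waveform needs >= 8 phases, got {self.n_phases}")
        if not self.period > 0:
            raise ValueError("waveform period must be positive")

    @property
    def n_phases(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.period / self.n_phases

    def sample(self, t) -> np.ndarray:
        """Periodic linear interpolation at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        tau = np.mod(t, self.period)
        x = tau * self.n_phases / self.period
        i0 = np.floor(x).astype(int) % self.n_phases
        i1 = (i0 + 1) % self.n_phases
        w = x - np.floor(x)
        return (1.0 - w) * self.values[i0] + w * self.values[i1]

    def resample(self, n: int) -> "Waveform":
        """Resample to ``n`` uniform phases by periodic linear interpolation."""
        if n < 8:
            raise ValueError("cannot resample below 8 phases")
        tt = np.arange(n) * self.period / n
        return Waveform(self.sample(tt), self.period)

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class PatientRecord:
    """Scalar demographics plus MRI- and catheterization-derived metrics."""

    subject_id: str
    age: Optional[float] = None
    bsa: Optional[float] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    who_fc: Optional[str] = None
    mri_metrics: dict = field(default_factory=dict)
    cath_metrics: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.bsa is not None and not self.bsa > 0:
            raise ValueError("BSA must be positive")
        for key in ("rv_ef_pct", "lv_ef_pct"):
            ef = self.mri_metrics.get(key)
            if ef is not None and not (0 < ef < 100):
                raise ValueError(f"{key} out of (0, 100): {ef}")
        for side in ("rv", "lv"):
            edv = self.mri_metrics.get(f"{side}_edv_ml")
            esv = self.mri_metrics.get(f"{side}_esv_ml")
            sv = self.mri_metrics.get(f"{side}_sv_ml")
            if edv is not None and esv is not None and sv is not None:
                if abs((edv - esv) - sv) > 1.0 + 1e-9:
                    raise ValueError(
                        f"{side} stroke volume inconsistent with EDV-ESV beyond 1 ml"
                    )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PatientRecord":
        return cls(**json.loads(text))


@dataclass
class ClinicalBundle:
    """Per-patient waveform bundle: 40-phase flows, 30-phase volumes,
    catheter pressures, plus the scalar record and optional severity rank."""

    record: PatientRecord
    flows: dict = field(default_factory=dict)       # site -> Waveform (ml/s)
    volumes: dict = field(default_factory=dict)     # chamber -> Waveform (ml)
    pressures: dict = field(default_factory=dict)   # site -> Waveform (mmHg)
    severity_rank: Optional[int] = None

    def validate(self) -> None:
        for name, wf in self.volumes.items():
            if wf.n_phases != 30:
                raise ValueError(f"volume waveform {name} must have 30 phases")
        for name, wf in self.flows.items():
            if wf.n_phases != 40:
                raise ValueError(f"flow waveform {name} must have 40 phases")
        for group in (self.flows, self.volumes, self.pressures):
            periods = {round(wf.period, 9) for wf in group.values()}
            if len(periods) > 1:
                raise ValueError("waveforms of one modality must share a period")


@dataclass
class CohortFixture:
    """The embedded eight-subject cohort with severity ranks and the
    reported correlation table."""

    records: list
    severity: dict
    reported_correlations: dict

    def record(self, subject_id: int) -> PatientRecord:
        return self.records[subject_id - 1]


def load_cohort_fixture() -> CohortFixture:
    """Build the embedded cohort: eight patient records, the clinical
    severity ranking (permutation of 1..8), and reported correlations."""
    records = []
    for i, sid in enumerate(cohort_data.SUBJECT_IDS):
        demo = cohort_data.DEMOGRAPHICS
        rec = PatientRecord(
            subject_id=f"Subject #{sid}",
            age=demo["age_years"][i],
            bsa=demo["bsa_m2"][i],
            height=demo["height_cm"][i],
            weight=demo["weight_kg"][i],
            who_fc=demo["who_fc"][i],
            mri_metrics={k: v[i] for k, v in cohort_data.MRI_METRICS.items()},
            cath_metrics={k: v[i] for k, v in cohort_data.CATH_METRICS.items()},
        )
        rec.validate()
        records.append(rec)
    ranks = sorted(cohort_data.SEVERITY_RANK.values())
    assert ranks == list(range(1, 9)), "severity ranks must be a permutation of 1..8"
    return CohortFixture(
        records=records,
        severity=dict(cohort_data.SEVERITY_RANK),
        reported_correlations=dict(cohort_data.REPORTED_CORRELATIONS),
    )


def write_waveform_csv(waveform: Waveform, path) -> None:
    """Write a waveform as a two-column (time s, value) CSV at full precision."""
    t = waveform.times
    with open(path, "w") as fh:
        fh.write("time,value\n")
        for ti, vi in zip(t, waveform.values):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def read_waveform_csv(path) -> Waveform:
    """Read a two-column (time s, value) CSV into a :class:`Waveform`.

    The time column must be a uniform grid starting at 0 covering one
    period; jitter above 1e-6 s is a format error.
    """
    data = np.genfromtxt(path, delimiter=",", skip_header=1, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise WaveformFormatError("expected a two-column (time,value) CSV")
    if data.shape[0] < 8:
        raise WaveformFormatError("waveform CSV needs at least 8 rows")
    t, v = data[:, 0], data[:, 1]
    n = len(t)
    dt = t[1] - t[0]
    if dt <= 0:
        raise WaveformFormatError("time column must be increasing")
    expected = t[0] + dt * np.arange(n)
    if np.max(np.abs(t - expected)) > 1e-6:
        raise WaveformFormatError("time column deviates from a uniform grid by > 1e-6 s")
    period = dt * n
    return Waveform(v, period)


def _maybe(f):
    """Evaluate a metric thunk, returning None when inputs are missing."""
    try:
        out = f()
    except (KeyError, TypeError):
        return None
    if out is None or (isinstance(out, float) and math.isnan(out)):
        return None
    return out


def derived_scalar_metrics(record: PatientRecord) -> dict:
    """Recompute the derivable scalar metrics from a patient record.

    Returns averaged cardiac output (L/min), cardiac index (L/min/m^2),
    stroke volumes and ejection fractions per ventricle, BSA-indexed
    volumes/masses (per m^2), PVRi ((mPAP-PCWP)/CI, WU*m^2) and MPA
    diastolic pressure (systolic - pulse).  Metrics whose inputs are
    missing are simply absent from the result.
    """
    m, c = record.mri_metrics, record.cath_metrics
    bsa = record.bsa
    out: dict = {}

    def put(name, thunk):
        val = _maybe(thunk)
        if val is not None:
            out[name] = val

    put("averaged_co_lmin", lambda: (m["aorta_flow_lmin"] + m["mpa_flow_lmin"]) / 2.0)
    put("cardiac_index_lmin_m2",
        lambda: (m["aorta_flow_lmin"] + m["mpa_flow_lmin"]) / 2.0 / bsa)
    for side in ("rv", "lv"):
        put(f"{side}_sv_ml", lambda s=side: m[f"{s}_edv_ml"] - m[f"{s}_esv_ml"])
        put(f"{side}_ef_pct",
            lambda s=side: (m[f"{s}_edv_ml"] - m[f"{s}_esv_ml"]) / m[f"{s}_edv_ml"] * 100.0)
        put(f"{side}_edvi_ml_m2", lambda s=side: m[f"{s}_edv_ml"] / bsa)
        put(f"{side}_esvi_ml_m2", lambda s=side: m[f"{s}_esv_ml"] / bsa)
        # indexed SV prefers the reported SV cell (the published index was
        # computed from it) and falls back to EDV - ESV
        put(f"{side}_svi_ml_m2",
            lambda s=side: (m[f"{s}_sv_ml"]
                            if m.get(f"{s}_sv_ml") is not None
                            else m[f"{s}_edv_ml"] - m[f"{s}_esv_ml"]) / bsa)
        put(f"{side}_mass_index_g_m2", lambda s=side: m[f"{s}_mass_g"] / bsa)
    put("pvri_wu_m2",
        lambda: (c["mpap_mmhg"] - c["pcwp_mmhg"])
        / ((m["aorta_flow_lmin"] + m["mpa_flow_lmin"]) / 2.0 / bsa))
    put("mpa_diastolic_mmhg", lambda: c["pa_systolic_mmhg"] - c["pa_pulse_mmhg"])
    return out


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero to the printed precision of a table cell."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1.0 if x >= 0 else -1.0)
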