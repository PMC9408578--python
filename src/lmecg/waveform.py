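"""Signal-level grounding of the ST-deviation convention.

Synthesises 12-lead ECG-like beats from a sum-of-Gaussian-bumps
morphology (P, Q, R, S, T) with a programmable ST plateau and QRS width,
and measures ST deviation back from the samples. The measurement
convention is the clinical one: mean amplitude in a +-10 ms window at
J + 60 ms (configurable 40-80 ms), referenced to the median of the PR
segment. Amplitudes are in mm of trace deflection (1 mm = 0.1 mV).

Fiducials (P onset, QRS onset, J point, T end) are carried as ground
truth from the generator — this module demonstrates the measurement
convention, it is not a delineation algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .feature_model import (
    ConductionFlags,
    ECGFeatureRecord,
    LEADS,
    Lead,
    STDeviationVector,
    Sex,
)

__all__ = [
    "BeatParams",
    "FiducialMap",
    "synthesize_beat",
    "measure_st",
    "record_from_waveforms",
]


@dataclass(frozen=True)
class BeatParams:
    """Morphology and acquisition parameters for synthetic beats."""

    heart_rate_bpm: float = 60.0
    qrs_ms: float = 100.0
    st_offset_mm: float = 0.0
    sampling_rate_hz: float = 500.0
    noise_sd_mm: float = 0.0
    n_beats: int = 1

    def __post_init__(self) -> None:
        if self.sampling_rate_hz < 250.0:
            raise ValueError("sampling rate must be >= 250 Hz")
        if not (40.0 <= self.qrs_ms <= 300.0):
            raise ValueError(f"qrs_ms out of [40, 300]: {self.qrs_ms}")
        if self.noise_sd_mm < 0:
            raise ValueError("noise SD must be >= 0")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")
        if not (20.0 <= self.heart_rate_bpm <= 250.0):
            raise ValueError(f"implausible heart rate: {self.heart_rate_bpm}")


@dataclass(frozen=True)
class FiducialMap:
    """Per-beat sample indices of the landmarks used for measurement."""

    p_onset: tuple
    qrs_onset: tuple
    j_point: tuple
    t_end: tuple
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.p_onset)
        if not (len(self.qrs_onset) == len(self.j_point) == len(self.t_end) == n):
            raise ValueError("fiducial vectors must have equal length")
        for p, q, j, t in zip(self.p_onset, self.qrs_onset, self.j_point, self.t_end):
            if not (p < q < j < t):
                raise ValueError("fiducials must be strictly increasing within a beat")


def _gauss(t: np.ndarray, centre: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - centre) / sigma) ** 2)


def _smooth_box(t: np.ndarray, lo: float, hi: float, ramp: float) -> np.ndarray:
    """Unit plateau on [lo, hi] with raised-cosine ramps of width ``ramp``."""
    out = np.zeros_like(t)
    rising = (t >= lo) & (t < lo + ramp)
    out[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - lo) / ramp))
    out[(t >= lo + ramp) & (t <= hi)] = 1.0
    falling = (t > hi) & (t < hi + ramp)
    out[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - hi) / ramp))
    return out


# per-lead R-wave amplitudes (mm): crude but lead-dependent morphology
_R_AMP = {
    Lead.I: 8.0, Lead.II: 10.0, Lead.III: 5.0, Lead.aVR: -6.0, Lead.aVL: 5.0,
    Lead.aVF: 7.0, Lead.V1: -4.0, Lead.V2: 6.0, Lead.V3: 10.0, Lead.V4: 14.0,
    Lead.V5: 12.0, Lead.V6: 10.0,
}


def synthesize_beat(
    params: BeatParams,
    lead: Lead = Lead.II,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, FiducialMap]:
    """Synthesise ``n_beats`` concatenated beats for one lead.

    Each beat carries a P wave, a QRS complex whose onset-to-J span equals
    ``qrs_ms`` exactly, an ST plateau at ``st_offset_mm`` between J and T
    end, and a T wave; Gaussian noise of the requested SD is added on top.
    The wave widths are chosen so bump tails are numerically negligible
    (< 1e-8 mm) inside both the PR baseline window and the ST measurement
    window.
    """
    fs = params.sampling_rate_hz
    beat_s = 60.0 / params.heart_rate_bpm
    qrs_s = params.qrs_ms / 1000.0
    n_per_beat = int(round(beat_s * fs))
    t = np.arange(n_per_beat) / fs

    p_onset_s = 0.08
    p_centre = p_onset_s + 0.05
    qrs_onset_s = 0.26
    j_s = qrs_onset_s + qrs_s
    t_end_s = min(j_s + 0.42, beat_s - 0.05)
    if t_end_s - j_s < 0.25:
        raise ValueError(
            "beat too short for the requested QRS: lower the heart rate "
            "or shorten the QRS"
        )
    t_centre = t_end_s - 0.08

    r_amp = _R_AMP[lead]
    r_centre = qrs_onset_s + qrs_s / 2.0
    qrs_sigma = qrs_s / 10.0
    beat = (
        _gauss(t, p_centre, 0.012, 1.0)
        + _gauss(t, r_centre, qrs_sigma, r_amp)
        + _gauss(t, qrs_onset_s + qrs_s * 0.2, qrs_sigma / 2.0, -0.12 * r_amp)
        + _gauss(t, qrs_onset_s + qrs_s * 0.8, qrs_sigma / 2.0, -0.2 * r_amp)
        + _gauss(t, t_centre, 0.022, 0.25 * abs(r_amp))
        + params.st_offset_mm * _smooth_box(t, j_s, t_end_s, 0.02)
    )

    signal = np.tile(beat, params.n_beats)
    if params.noise_sd_mm > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, params.noise_sd_mm, size=signal.size)

    starts = np.arange(params.n_beats) * n_per_beat
    fid = FiducialMap(
        p_onset=tuple(int(s + round(p_onset_s * fs)) for s in starts),
        qrs_onset=tuple(int(s + round(qrs_onset_s * fs)) for s in starts),
        j_point=tuple(int(s + round(qrs_onset_s * fs) + round(qrs_s * fs))
                      for s in starts),
        t_end=tuple(int(s + round(t_end_s * fs)) for s in starts),
        sampling_rate_hz=fs,
    )
    return signal, fid


def measure_st(
    signal: np.ndarray,
    fiducials: FiducialMap,
    j_offset_ms: float = 60.0,
) -> float:
    """Measure ST deviation in mm, averaged across beats.

    Per beat: mean amplitude over a +-10 ms window centred at
    J + ``j_offset_ms``, minus the median of the PR segment (from 50 ms
    before QRS onset to 20 ms before it). Beats are averaged.
    """
    if not (40.0 <= j_offset_ms <= 80.0):
        raise ValueError(f"j_offset_ms out of [40, 80]: {j_offset_ms}")
    fs = fiducials.sampling_rate_hz
    half = int(round(0.010 * fs))
    values = []
    for q, j in zip(fiducials.qrs_onset, fiducials.j_point):
        centre = j + int(round(j_offset_ms / 1000.0 * fs))
        lo, hi = centre - half, centre + half + 1
        pr_lo = q - int(round(0.050 * fs))
        pr_hi = q - int(round(0.020 * fs))
        if lo < 0 or hi > signal.size or pr_lo < 0:
            raise ValueError("measurement window falls outside the signal")
        baseline = float(np.median(signal[pr_lo:pr_hi]))
        values.append(float(np.mean(signal[lo:hi])) - baseline)
    return float(np.mean(values))


def record_from_waveforms(
    signals: Mapping[Lead, np.ndarray],
    fiducials: FiducialMap,
    sex: Sex,
    conduction: ConductionFlags = ConductionFlags(),
    *,
    record_id: str = "wf-0",
    j_offset_ms: float = 60.0,
) -> ECGFeatureRecord:
    """Assemble a feature record from 12 lead signals with shared fiducials."""
    missing = [ld.name for ld in LEADS if ld not in signals]
    if missing:
        raise ValueError(f"missing lead signals: {missing}")
    st = {ld: measure_st(signals[ld], fiducials, j_offset_ms) for ld in LEADS}
    qrs_ms = (
        (fiducials.j_point[0] - fiducials.qrs_onset[0])
        / fiducials.sampling_rate_hz * 1000.0
    )
    return ECGFeatureRecord(
        id=record_id,
        sex=sex,
        st=STDeviationVector(st),
        qrs_ms=qrs_ms,
        conduction=conduction,
    )
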