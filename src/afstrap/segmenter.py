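"""Model-input preparation: resample to 125 Hz, cut non-overlapping 10-s
windows with the single lead replicated across 3 channels, and compute
per-window signal-quality features used by the classifier's quality gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import List

import numpy as np
from scipy import signal as sps

from .core import SEGMENT_S, EcgRecord

#: Sampling rate (Hz) and samples per window the classifier expects.
MODEL_FS = 125.0
SAMPLES_PER_SEGMENT = int(SEGMENT_S * MODEL_FS)  # 1250


@dataclass
class SegmentInput:
    """One 10-second window in model-input form (3 identical channels)."""

    patient_id: str
    index: int
    t_start_s: float
    t_end_s: float
    channels: np.ndarray  # shape (3, n), identical rows
    fs: float = MODEL_FS

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 3:
            raise ValueError("channels must have shape (3, n)")

    @property
    def signal(self) -> np.ndarray:
        return self.channels[0]


@dataclass(frozen=True)
class QualityFeatures:
    flatline_fraction: float
    amplitude_range: float
    hf_noise_ratio: float
    clipping_fraction: float


def resample_record(record: EcgRecord, fs_target: float = MODEL_FS) -> EcgRecord:
    """Anti-aliased rational resampling (polyphase) to ``fs_target``.

    A record already at the target rate is returned with its samples
    unchanged.  Duration is preserved to within one output sample.
    """
    if fs_target <= 0:
        raise ValueError(f"fs_target must be positive, got {fs_target}")
    if record.fs < fs_target:
        raise ValueError(
            f"record fs {record.fs} Hz below target {fs_target} Hz; "
            "upsampling is not supported"
        )
    if abs(record.fs - fs_target) < 1e-9:
        return record
    frac = Fraction(fs_target / record.fs).limit_denominator(10000)
    y = sps.resample_poly(record.samples, frac.numerator, frac.denominator)
    return EcgRecord(patient_id=record.patient_id, fs=fs_target, samples=y,
                     t0=record.t0)


def segment_record(record: EcgRecord) -> List[SegmentInput]:
    """Cut a 125 Hz record into consecutive non-overlapping 10-s windows.

    Windows are aligned to the recording start; a trailing partial window
    is dropped.  A record shorter than one window yields an empty list.
    """
    if abs(record.fs - MODEL_FS) > 1e-9:
        raise ValueError(f"segment_record expects {MODEL_FS} Hz, got {record.fs}")
    n_per = SAMPLES_PER_SEGMENT
    n_win = record.samples.size // n_per
    out = []
    for i in range(n_win):
        x = record.samples[i * n_per:(i + 1) * n_per]
        t0 = record.t0 + i * SEGMENT_S
        out.append(SegmentInput(patient_id=record.patient_id, index=i,
                                t_start_s=t0, t_end_s=t0 + SEGMENT_S,
                                channels=np.vstack([x, x, x])))
    return out


def _longest_flat_run(x: np.ndarray, eps: float) -> int:
    """Length (in samples) of the longest run of near-constant signal."""
    flat = np.abs(np.diff(x)) < eps
    best = run = 0
    for f in flat:
        run = run + 1 if f else 0
        best = max(best, run)
    return best + 1 if best else 1


def quality_features(segment: SegmentInput, flat_eps: float = 1.0) -> QualityFeatures:
    """Deterministic per-window quality summary.

    ``flatline_fraction`` is the longest near-constant run over the window
    length; ``hf_noise_ratio`` is power above 40 Hz divided by power in
    0.5-40 Hz (0 for an all-zero window); ``clipping_fraction`` is the
    share of samples pinned within 1% of the window extremes.
    """
    x = segment.signal
    n = x.size
    flat = _longest_flat_run(x, flat_eps) / n
    rng_uv = float(np.ptp(x))
    f = np.fft.rfftfreq(n, d=1.0 / segment.fs)
    p = np.abs(np.fft.rfft(x - x.mean())) ** 2
    lo = float(p[(f >= 0.5) & (f < 40.0)].sum())
    hi = float(p[f >= 40.0].sum())
    hf = hi / lo if lo > 0 else 0.0
    if rng_uv > 0:
        margin = 0.01 * rng_uv
        clip = float(np.mean((x >= x.max() - margin) | (x <= x.min() + margin)))
    else:
        clip = 0.0
    return QualityFeatures(flatline_fraction=float(flat), amplitude_range=rng_uv,
                           hf_noise_ratio=hf, clipping_fraction=clip)
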