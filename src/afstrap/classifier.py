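"""Rule-based 10-second segment classifier.

Fulfils the three-class segment-classification contract — AF/AFL,
non-AF/AFL, noninterpretable — with a transparent detector: a signal
quality gate, R-peak detection, RR-interval irregularity statistics
(coefficient of variation and normalized RMSSD), and a flutter-wave
periodicity check for the regular-RR presentation of AFL.  Any model
exposing ``classify_segment(segment) -> SegmentLabel`` can be substituted
for it; downstream postprocessing and metrics only see segment labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .core import (AF, AFL, AFIB_FLUTTER, NOISE, NON_AF, SR, UNINTERPRETABLE,
                   EcgRecord, RhythmTimeline, SegmentLabel)
from .segmenter import (MODEL_FS, QualityFeatures, SegmentInput,
                        quality_features, resample_record, segment_record)


@dataclass
class ClassifierParams:
    """Thresholds of the rule-based baseline classifier.

    Quality gate (any failure makes the window noninterpretable):
    ``max_flatline_fraction``, ``max_hf_noise_ratio``,
    ``min_amplitude_range`` / ``max_amplitude_range`` (µV), and
    ``min_beats`` detected R peaks.  Rhythm decision: a window is AF/AFL
    when both RR-irregularity statistics exceed their thresholds, or when
    the flutter heuristic fires (near-constant RR at a rate consistent
    with 2:1 conduction plus a 3.5-6.5 Hz flutter-wave spectral peak in
    the QRS-cancelled residual).
    """

    max_flatline_fraction: float = 0.4
    max_hf_noise_ratio: float = 0.25
    min_amplitude_range: float = 300.0
    max_amplitude_range: float = 4000.0
    min_beats: int = 4
    cv_rr_threshold: float = 0.12
    nsd_rr_threshold: float = 0.10
    flutter_rate_bpm: Tuple[float, float] = (120.0, 165.0)
    flutter_cv_max: float = 0.06
    flutter_band_hz: Tuple[float, float] = (3.5, 6.5)
    flutter_power_ratio: float = 0.35


@lru_cache(maxsize=8)
def _qrs_sos(fs: float):
    return sps.butter(3, [5.0, 30.0], btype="bandpass", fs=fs, output="sos")


def detect_r_peaks(segment: SegmentInput,
                   min_peak_uv: float = 100.0) -> np.ndarray:
    """R-peak times (seconds, absolute) within one window.

    Band-passes to the QRS band (5-30 Hz), thresholds at 45% of the
    window maximum, and enforces a 0.2-s refractory period.  Windows with
    no content above ``min_peak_uv`` yield no peaks.
    """
    x = segment.signal
    fs = segment.fs
    f = sps.sosfiltfilt(_qrs_sos(fs), x)
    peak_ceiling = float(np.max(np.abs(f))) if f.size else 0.0
    if peak_ceiling < min_peak_uv:
        return np.empty(0)
    idx, _ = sps.find_peaks(f, height=0.45 * peak_ceiling,
                            distance=max(1, int(round(0.2 * fs))))
    return segment.t_start_s + idx / fs


def rr_features(peaks: Sequence[float]) -> Tuple[float, float, int]:
    """RR irregularity statistics: ``(cv_rr, nsd_rr, n_beats)``.

    ``cv_rr`` = SD(RR)/mean(RR); ``nsd_rr`` = RMS of successive RR
    differences divided by mean RR.  Both are 0 with fewer than 3 RR
    intervals.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size and np.any(np.diff(peaks) <= 0):
        raise ValueError("peak times must be strictly increasing")
    rr = np.diff(peaks)
    if rr.size < 3:
        return 0.0, 0.0, int(peaks.size)
    mean_rr = float(rr.mean())
    cv = float(rr.std() / mean_rr)
    nsd = float(np.sqrt(np.mean(np.diff(rr) ** 2)) / mean_rr)
    return cv, nsd, int(peaks.size)


def _flutter_wave_score(segment: SegmentInput, peaks: np.ndarray,
                        params: ClassifierParams) -> float:
    """Share of 1-10 Hz residual power in the flutter band.

    QRS complexes are cancelled (±50 ms around each R peak replaced by
    linear interpolation) before the spectrum is taken, so the score
    reflects atrial rather than ventricular periodicity.
    """
    x = segment.signal.copy()
    fs = segment.fs
    rel = ((peaks - segment.t_start_s) * fs).astype(int)
    half = int(round(0.05 * fs))
    for r in rel:
        i0, i1 = max(0, r - half), min(x.size - 1, r + half)
        if i1 > i0:
            x[i0:i1 + 1] = np.linspace(x[i0], x[i1], i1 - i0 + 1)
    freqs, psd = sps.welch(x - x.mean(), fs=fs, nperseg=min(512, x.size))
    lo, hi = params.flutter_band_hz
    band = float(psd[(freqs >= lo) & (freqs <= hi)].sum())
    total = float(psd[(freqs >= 1.0) & (freqs <= 10.0)].sum())
    return band / total if total > 0 else 0.0


def decide_rhythm(cv_rr: float, nsd_rr: float, n_beats: int,
                  mean_rate_bpm: float, flutter_score: float,
                  params: ClassifierParams) -> Tuple[str, float]:
    """Pure decision rule mapping RR statistics to a rhythm label.

    Returns ``(label, score)`` where score is the AF/AFL confidence.
    Raising ``cv_rr`` with everything else fixed can only move the label
    from non-AF/AFL toward AF/AFL, never the reverse.
    """
    if n_beats < params.min_beats:
        return UNINTERPRETABLE, 0.0
    irregular = cv_rr > params.cv_rr_threshold and nsd_rr > params.nsd_rr_threshold
    lo_bpm, hi_bpm = params.flutter_rate_bpm
    # flutter path depends on rate and atrial periodicity only, so that
    # increasing cv_rr can never move AF/AFL back to non-AF/AFL
    flutter = (lo_bpm <= mean_rate_bpm <= hi_bpm
               and flutter_score > params.flutter_power_ratio)
    if irregular:
        margin = min(cv_rr - params.cv_rr_threshold,
                     nsd_rr - params.nsd_rr_threshold)
        return AFIB_FLUTTER, float(np.clip(0.5 + 5.0 * margin, 0.5, 1.0))
    if flutter:
        return AFIB_FLUTTER, 0.9
    return NON_AF, float(np.clip(0.5 * cv_rr / params.cv_rr_threshold, 0.0, 0.49))


def classify_segment(segment: SegmentInput,
                     params: Optional[ClassifierParams] = None) -> SegmentLabel:
    """Classify one 10-s window into AF/AFL, non-AF/AFL or noninterpretable.

    The quality gate runs first: a window failing any quality threshold is
    noninterpretable regardless of its RR statistics.
    """
    params = params or ClassifierParams()
    qf = quality_features(segment)
    if (qf.flatline_fraction > params.max_flatline_fraction
            or qf.hf_noise_ratio > params.max_hf_noise_ratio
            or qf.amplitude_range < params.min_amplitude_range
            or qf.amplitude_range > params.max_amplitude_range):
        return _label(segment, UNINTERPRETABLE, 0.0)
    peaks = detect_r_peaks(segment)
    cv, nsd, n_beats = rr_features(peaks)
    if n_beats < params.min_beats:
        return _label(segment, UNINTERPRETABLE, 0.0)
    duration = peaks[-1] - peaks[0]
    rate = 60.0 * (n_beats - 1) / duration if duration > 0 else 0.0
    # the RR-regularity gate for the flutter path: only near-constant RR
    # warrants the atrial-periodicity check
    fl = _flutter_wave_score(segment, peaks, params) \
        if cv < params.flutter_cv_max else 0.0
    label, score = decide_rhythm(cv, nsd, n_beats, rate, fl, params)
    return _label(segment, label, score)


def _label(segment: SegmentInput, label: str, score: float) -> SegmentLabel:
    return SegmentLabel(patient_id=segment.patient_id, index=segment.index,
                        t_start_s=segment.t_start_s, t_end_s=segment.t_end_s,
                        label=label, score=score)


def classify_record(record: EcgRecord,
                    params: Optional[ClassifierParams] = None) -> List[SegmentLabel]:
    """Resample to 125 Hz, window, and classify a whole recording."""
    rec125 = resample_record(record, MODEL_FS)
    return [classify_segment(s, params) for s in segment_record(rec125)]


_REF_MAP = {AF: AF, AFL: AFL, SR: NON_AF, NOISE: UNINTERPRETABLE}


def label_reference_segment(reference: RhythmTimeline, t_start: float,
                            t_end: float) -> str:
    """Reference class of a window: AF, AFL, NON_AF or UNINTERPRETABLE.

    The window takes the class of the timeline interval covering the
    majority of it; ties go to the earlier interval.  AF and AFL are kept
    distinct so arrhythmia-specific sensitivities stay computable.
    """
    return _REF_MAP[reference.majority_label(t_start, t_end)]
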