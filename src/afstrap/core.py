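"""Core domain types shared by every pipeline stage.

Conventions: all times are seconds from recording start, intervals are
half-open ``[start, end)``, and amplitudes are microvolts.  Rhythm
timelines must tile the recording exactly (contiguous, non-overlapping,
covering ``[0, duration]``), which keeps window arithmetic exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

# Reference (timeline) rhythm vocabulary.
AF = "AF"
AFL = "AFL"
SR = "SR"
NOISE = "NOISE"
TIMELINE_LABELS = (AF, AFL, SR, NOISE)

# Classifier output vocabulary: the three classes a 10-s segment can get.
AFIB_FLUTTER = "AFIB_FLUTTER"
NON_AF = "NON_AF"
UNINTERPRETABLE = "UNINTERPRETABLE"
PRED_CLASSES = (AFIB_FLUTTER, NON_AF, UNINTERPRETABLE)

# Reference classes used in duration confusion matrices: AF and AFL are
# kept distinct so AF-only and AFL-only sensitivities stay computable.
REF_CLASSES = (AF, AFL, NON_AF, UNINTERPRETABLE)

#: Window length of one classified segment, seconds.
SEGMENT_S = 10.0


@dataclass
class EcgRecord:
    """A uniformly sampled single-lead ECG waveform.

    Parameters
    ----------
    patient_id : str
        Identifier of the patient the recording belongs to.
    fs : float
        Sampling rate in Hz; must be positive.
    samples : ndarray
        Amplitude series in microvolts; finite values only.
    t0 : float
        Offset of the first sample from recording start, seconds.
    """

    patient_id: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite amplitudes")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class RhythmTimeline:
    """Ordered, contiguous, labeled rhythm intervals covering a recording.

    ``intervals`` is a sequence of ``(start_s, end_s, label)`` with labels
    drawn from :data:`TIMELINE_LABELS`.  Construction validates coverage:
    the first interval starts at 0, each interval starts where the
    previous ended, and every interval has positive length.
    """

    intervals: tuple = field(default_factory=tuple)

    def __init__(self, intervals: Sequence) -> None:
        ivs = tuple((float(s), float(e), str(lab)) for s, e, lab in intervals)
        if not ivs:
            raise ValueError("timeline must contain at least one interval")
        if abs(ivs[0][0]) > 1e-9:
            raise ValueError(f"timeline must start at 0, starts at {ivs[0][0]}")
        prev_end = ivs[0][0]
        for i, (s, e, lab) in enumerate(ivs):
            if lab not in TIMELINE_LABELS:
                raise ValueError(f"interval {i}: unknown label {lab!r}")
            if e <= s:
                raise ValueError(f"interval {i}: end {e} <= start {s}")
            if abs(s - prev_end) > 1e-9:
                raise ValueError(
                    f"interval {i}: start {s} != previous end {prev_end} "
                    "(timeline must be contiguous)"
                )
            prev_end = e
        object.__setattr__(self, "intervals", ivs)

    def __iter__(self) -> Iterator:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration_s(self) -> float:
        return self.intervals[-1][1]

    def label_at(self, t: float) -> str:
        """Label of the interval containing time ``t`` (half-open intervals)."""
        if t < 0 or t >= self.duration_s:
            raise ValueError(f"t={t} outside timeline span [0, {self.duration_s})")
        for s, e, lab in self.intervals:
            if s <= t < e:
                return lab
        raise AssertionError("unreachable: contiguous timeline")

    def majority_label(self, t_start: float, t_end: float) -> str:
        """Label covering the majority of window ``[t_start, t_end)``.

        Ties go to the earlier interval.  The window must lie within the
        timeline span.
        """
        if t_start < -1e-9 or t_end > self.duration_s + 1e-9 or t_end <= t_start:
            raise ValueError(
                f"window [{t_start}, {t_end}) outside timeline span "
                f"[0, {self.duration_s}]"
            )
        best_lab, best_ov, best_start = None, -1.0, None
        for s, e, lab in self.intervals:
            ov = min(e, t_end) - max(s, t_start)
            if ov > best_ov + 1e-12:
                best_lab, best_ov, best_start = lab, ov, s
        assert best_lab is not None
        return best_lab

    def durations_by_label(self) -> dict:
        out: dict = {}
        for s, e, lab in self.intervals:
            out[lab] = out.get(lab, 0.0) + (e - s)
        return out

    def coalesced(self) -> "RhythmTimeline":
        """Merge adjacent intervals that share a label."""
        merged = [list(self.intervals[0])]
        for s, e, lab in self.intervals[1:]:
            if lab == merged[-1][2]:
                merged[-1][1] = e
            else:
                merged.append([s, e, lab])
        return RhythmTimeline(tuple((s, e, lab) for s, e, lab in merged))


@dataclass(frozen=True)
class SegmentLabel:
    """Classification of one 10-second window."""

    patient_id: str
    index: int
    t_start_s: float
    t_end_s: float
    label: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in PRED_CLASSES:
            raise ValueError(f"label must be one of {PRED_CLASSES}, got {self.label!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass(frozen=True)
class Episode:
    """A postprocessed contiguous AF/AFL span (minimum 30 s by default)."""

    patient_id: str
    t_start_s: float
    t_end_s: float
    label: str = AFIB_FLUTTER

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s
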