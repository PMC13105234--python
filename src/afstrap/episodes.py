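"""Episode postprocessing, AF/AFL burden, and rhythm-change delay.

Consecutive AF/AFL windows are combined into candidate episodes,
closely spaced candidates separated by short gaps are merged (gap time
included in the span), and candidates still shorter than 30 s are
discarded — aligning with the guideline definition that requires at
least 30 s of continuous single-lead ECG for an AF diagnosis.  Merging
runs before the minimum-duration filter so that two sub-30-s runs
separated by a short gap survive as one episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence

from .core import (AF, AFL, AFIB_FLUTTER, NON_AF, SR, UNINTERPRETABLE,
                   Episode, RhythmTimeline, SegmentLabel)


@dataclass
class PostprocessParams:
    """Episode postprocessing knobs.

    ``min_episode_s``: minimum surviving episode length (default 30 s,
    i.e. 3 windows).  ``max_gap_s``: longest non-AF/AFL gap that may be
    bridged between candidates (default 30 s, symmetric with the
    minimum).  Gaps consisting purely of noninterpretable windows are
    bridgeable regardless of length by default — noise inside an AF
    episode should not split it — while gaps containing non-AF/AFL
    windows are bridged only up to ``max_gap_s``.
    """

    min_episode_s: float = 30.0
    max_gap_s: float = 30.0
    bridgeable: FrozenSet[str] = frozenset({NON_AF, UNINTERPRETABLE})
    bridge_uninterpretable_any_gap: bool = True

    def __post_init__(self) -> None:
        if self.min_episode_s <= 0:
            raise ValueError("min_episode_s must be positive")
        if self.max_gap_s < 0:
            raise ValueError("max_gap_s must be >= 0")


@dataclass(frozen=True)
class BurdenRecord:
    patient_id: str
    predicted_burden_h: float
    reference_burden_h: float


@dataclass(frozen=True)
class DelayRecord:
    """AF/AFL-to-SR rhythm-change detection delay for one transition.

    ``delay_s`` is defined only when a detected onset exists; a record
    with ``detected_sr_onset_s`` absent marks a transition the classifier
    never confirmed and is excluded from summaries.
    """

    patient_id: str
    ref_sr_onset_s: float
    detected_sr_onset_s: Optional[float]
    delay_s: Optional[float]

    @property
    def missing(self) -> bool:
        return self.detected_sr_onset_s is None


def _check_ordered(labels: Sequence[SegmentLabel]) -> None:
    pids = {l.patient_id for l in labels}
    if len(pids) > 1:
        raise ValueError(f"labels span multiple patients: {sorted(pids)}")
    for a, b in zip(labels, labels[1:]):
        if b.index <= a.index or b.t_start_s < a.t_end_s - 1e-9:
            raise ValueError("labels must be ordered by window index")


def build_episodes(labels: Sequence[SegmentLabel],
                   params: Optional[PostprocessParams] = None) -> List[Episode]:
    """Merge AF/AFL windows into episodes: runs -> gap merge -> 30-s filter."""
    params = params or PostprocessParams()
    labels = list(labels)
    if not labels:
        return []
    _check_ordered(labels)
    pid = labels[0].patient_id

    # (1) maximal runs of AF/AFL windows
    runs: List[List[float]] = []
    run_gap_labels: List[set] = []  # labels inside the gap before each run
    cur_gap: set = set()
    for lab in labels:
        if lab.label == AFIB_FLUTTER:
            if runs and not cur_gap and abs(runs[-1][1] - lab.t_start_s) < 1e-9:
                runs[-1][1] = lab.t_end_s
            else:
                runs.append([lab.t_start_s, lab.t_end_s])
                run_gap_labels.append(set(cur_gap))
                cur_gap = set()
        else:
            cur_gap.add(lab.label)

    # (2) merge candidates across bridgeable gaps
    merged: List[List[float]] = []
    for (s, e), gap_labs in zip(runs, run_gap_labels):
        if merged:
            gap = s - merged[-1][1]
            only_unint = gap_labs == {UNINTERPRETABLE}
            bridge = (gap_labs <= params.bridgeable and gap <= params.max_gap_s) or \
                     (params.bridge_uninterpretable_any_gap and only_unint)
            if bridge:
                merged[-1][1] = e
                continue
        merged.append([s, e])

    # (3) minimum-duration filter
    return [Episode(patient_id=pid, t_start_s=s, t_end_s=e)
            for s, e in merged if (e - s) >= params.min_episode_s - 1e-9]


def postprocessed_labels(labels: Sequence[SegmentLabel],
                         episodes: Sequence[Episode]) -> List[SegmentLabel]:
    """Project episodes back onto windows.

    Windows inside an episode become AF/AFL (including bridged-gap
    windows); AF/AFL windows outside every episode are reassigned
    non-AF/AFL; other windows are unchanged.
    """
    spans = [(ep.t_start_s, ep.t_end_s) for ep in episodes]
    out = []
    for lab in labels:
        mid = 0.5 * (lab.t_start_s + lab.t_end_s)
        inside = any(s <= mid < e for s, e in spans)
        if inside and lab.label != AFIB_FLUTTER:
            lab = SegmentLabel(lab.patient_id, lab.index, lab.t_start_s,
                               lab.t_end_s, AFIB_FLUTTER, lab.score)
        elif not inside and lab.label == AFIB_FLUTTER:
            lab = SegmentLabel(lab.patient_id, lab.index, lab.t_start_s,
                               lab.t_end_s, NON_AF, lab.score)
        out.append(lab)
    return out


def compute_burden(episodes: Sequence[Episode],
                   recording_duration_s: float) -> float:
    """Total AF/AFL episode time during the recording, in hours."""
    total_s = sum(ep.duration_s for ep in episodes)
    if total_s > recording_duration_s + 1e-6:
        raise ValueError("episode time exceeds recording duration")
    return total_s / 3600.0


def detection_delay(reference: RhythmTimeline,
                    post_labels: Sequence[SegmentLabel],
                    window_s: float = 10.0) -> DelayRecord:
    """Delay between the reference SR onset after AF/AFL and its detection.

    The reference onset is the start of the first SR interval following
    the initial AF/AFL period.  The detected onset is the start of the
    first postprocessed non-AF/AFL window beginning at or after the
    reference onset, with one window of slack for a window already
    non-AF/AFL that straddles the transition (so ``delay_s >= -10``).
    """
    pid = post_labels[0].patient_id if post_labels else "?"
    ivs = list(reference.intervals)
    i_af = next((i for i, (_, _, lab) in enumerate(ivs) if lab in (AF, AFL)), None)
    if i_af is None:
        raise ValueError("reference contains no AF/AFL period")
    ref_onset = next((s for s, _, lab in ivs[i_af + 1:] if lab == SR), None)
    if ref_onset is None:
        raise ValueError("reference contains no AF/AFL-to-SR transition")
    detected = next((l.t_start_s for l in post_labels
                     if l.label == NON_AF
                     and l.t_start_s >= ref_onset - window_s), None)
    if detected is None:
        return DelayRecord(pid, ref_onset, None, None)
    return DelayRecord(pid, ref_onset, detected, detected - ref_onset)
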