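"""Delimited-text readers/writers and run configuration.

Every artifact the pipeline touches is plain delimited text: ECG records
as two-column CSV (``t_s``, ``uV``), rhythm timelines as
(``patient_id``, ``start_s``, ``end_s``, ``label``) tables validated for
contiguity on read, segment-label / episode / burden / delay tables, and
a YAML run configuration that round-trips losslessly and rejects unknown
keys.  All writers and readers are inverse up to float formatting at
full precision.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .classifier import ClassifierParams
from .core import (PRED_CLASSES, TIMELINE_LABELS, EcgRecord, Episode,
                   RhythmTimeline, SegmentLabel)
from .episodes import BurdenRecord, DelayRecord, PostprocessParams
from .synthio import SimConfig

log = logging.getLogger("afstrap")

_FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# ECG records
# ---------------------------------------------------------------------------

def write_record(record: EcgRecord, path) -> None:
    """Write a record as CSV with columns ``t_s`` and ``uV``."""
    t = record.t0 + np.arange(record.samples.size) / record.fs
    pd.DataFrame({"t_s": t, "uV": record.samples}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_record(path, fmt: str = "csv",
                patient_id: Optional[str] = None) -> EcgRecord:
    """Read an ECG record; ``fmt='csv'`` expects columns ``t_s``, ``uV``.

    The sampling rate is inferred from the median time step and samples
    are asserted to be uniformly spaced.  WFDB input is not supported by
    this build and is rejected with a clear message.
    """
    if fmt == "wfdb":
        raise NotImplementedError(
            "WFDB input is not supported; convert to CSV (t_s, uV) first")
    if fmt != "csv":
        raise ValueError(f"unknown record format {fmt!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse record file {path}: {exc}") from exc
    missing = {"t_s", "uV"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) < 2:
        raise ValueError(f"{path}: truncated record (fewer than 2 samples)")
    dt = np.diff(df["t_s"].to_numpy())
    med = float(np.median(dt))
    if med <= 0 or np.any(np.abs(dt - med) > 0.01 * med):
        raise ValueError(f"{path}: non-uniform sampling (median dt {med})")
    fs = 1.0 / med
    return EcgRecord(patient_id=patient_id or path.stem, fs=round(fs, 6),
                     samples=df["uV"].to_numpy(), t0=float(df["t_s"].iloc[0]))


# ---------------------------------------------------------------------------
# Timelines
# ---------------------------------------------------------------------------

def write_timelines(timelines: Dict[str, RhythmTimeline], path) -> None:
    rows = [(pid, s, e, lab)
            for pid in sorted(timelines)
            for s, e, lab in timelines[pid].intervals]
    pd.DataFrame(rows, columns=["patient_id", "start_s", "end_s", "label"]) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_timelines(path) -> Dict[str, RhythmTimeline]:
    """Read a timeline table, enforcing contiguity and label vocabulary.

    Overlaps, gaps, or labels outside the vocabulary are rejected with
    the offending patient and rows named.
    """
    df = pd.read_csv(path)
    need = {"patient_id", "start_s", "end_s", "label"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    bad = sorted(set(df["label"]) - set(TIMELINE_LABELS))
    if bad:
        raise ValueError(f"{path}: labels outside vocabulary {TIMELINE_LABELS}: {bad}")
    out: Dict[str, RhythmTimeline] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        ivs = [(r.start_s, r.end_s, r.label)
               for r in grp.sort_values("start_s").itertuples()]
        try:
            out[str(pid)] = RhythmTimeline(ivs)
        except ValueError as exc:
            raise ValueError(f"{path}: invalid timeline for patient "
                             f"{pid} (rows {list(grp.index)}): {exc}") from exc
    return out


def write_timeline(timeline: RhythmTimeline, path,
                   patient_id: str = "P000") -> None:
    write_timelines({patient_id: timeline}, path)


def read_timeline(path) -> RhythmTimeline:
    tls = read_timelines(path)
    if len(tls) != 1:
        raise ValueError(f"{path}: expected exactly one patient, got {len(tls)}")
    return next(iter(tls.values()))


# ---------------------------------------------------------------------------
# Label / episode / burden / delay tables
# ---------------------------------------------------------------------------

def write_labels(labels: Dict[str, Sequence[SegmentLabel]], path) -> None:
    rows = [(l.patient_id, l.index, l.t_start_s, l.t_end_s, l.label, l.score)
            for pid in sorted(labels) for l in labels[pid]]
    pd.DataFrame(rows, columns=["patient_id", "index", "t_start_s", "t_end_s",
                                "label", "score"]) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_labels(path) -> Dict[str, List[SegmentLabel]]:
    df = pd.read_csv(path)
    bad = sorted(set(df["label"]) - set(PRED_CLASSES))
    if bad:
        raise ValueError(f"{path}: labels outside vocabulary {PRED_CLASSES}: {bad}")
    out: Dict[str, List[SegmentLabel]] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        out[str(pid)] = [
            SegmentLabel(str(pid), int(r["index"]), float(r["t_start_s"]),
                         float(r["t_end_s"]), r["label"], float(r["score"]))
            for _, r in grp.sort_values("index").iterrows()]
    return out


def write_episodes(episodes: Sequence[Episode], path) -> None:
    rows = [(e.patient_id, e.t_start_s, e.t_end_s, e.label) for e in episodes]
    pd.DataFrame(rows, columns=["patient_id", "start_s", "end_s", "label"]) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_burden(records: Sequence[BurdenRecord], path) -> None:
    rows = [(b.patient_id, b.predicted_burden_h, b.reference_burden_h)
            for b in records]
    pd.DataFrame(rows, columns=["patient_id", "predicted_h", "reference_h"]) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_delays(records: Sequence[DelayRecord], path) -> None:
    rows = [(d.patient_id, d.ref_sr_onset_s,
             "" if d.detected_sr_onset_s is None else d.detected_sr_onset_s,
             "" if d.delay_s is None else d.delay_s)
            for d in records]
    pd.DataFrame(rows, columns=["patient_id", "ref_sr_onset_s",
                                "detected_sr_onset_s", "delay_s"]) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full pipeline configuration; YAML round-trips losslessly."""

    sim: SimConfig = field(default_factory=SimConfig)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["postprocess"]["bridgeable"] = sorted(d["postprocess"]["bridgeable"])
        d["classifier"]["flutter_rate_bpm"] = list(d["classifier"]["flutter_rate_bpm"])
        d["classifier"]["flutter_band_hz"] = list(d["classifier"]["flutter_band_hz"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, sub):
            sub = dict(sub or {})
            names = {f.name for f in dataclasses.fields(klass)}
            extra = set(sub) - names
            if extra:
                raise ValueError(
                    f"unknown {klass.__name__} keys: {sorted(extra)}")
            if klass is PostprocessParams and "bridgeable" in sub:
                sub["bridgeable"] = frozenset(sub["bridgeable"])
            if klass is ClassifierParams:
                for k in ("flutter_rate_bpm", "flutter_band_hz"):
                    if k in sub:
                        sub[k] = tuple(sub[k])
            return klass(**sub)

        return cls(sim=build(SimConfig, d.get("sim")),
                   classifier=build(ClassifierParams, d.get("classifier")),
                   postprocess=build(PostprocessParams, d.get("postprocess")),
                   seed=int(d.get("seed", 0)),
                   log_level=str(d.get("log_level", "INFO")))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
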