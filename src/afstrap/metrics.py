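"""Diagnostic-accuracy statistics for the rhythm-analysis pipeline.

Time-based analysis pools 10-second windows into a duration-weighted
confusion matrix (hours) of predicted class — AF/AFL, non-AF/AFL,
noninterpretable — against reference class, with AF and AFL columns kept
separate so arrhythmia-specific sensitivities remain computable.
One-vs-rest metrics carry Wilson score intervals computed on the
window counts behind the hour totals (n = hours x 360).  F1 confidence
intervals use nonparametric bootstrap over patients (2000 iterations).
Episode-based (patient-level) detection yields a 2x2 confusion matrix
with Wilson CIs and the Youden index.  Burden agreement is assessed by
Bland-Altman bias with 95% limits of agreement and by the intraclass
correlation coefficient (two-way model, absolute agreement, single
measurements), and CHA2DS2-VA stroke-risk scoring is provided for
cohort description.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .core import (AF, AFL, AFIB_FLUTTER, NON_AF, PRED_CLASSES, REF_CLASSES,
                   SEGMENT_S, SR, UNINTERPRETABLE, RhythmTimeline, SegmentLabel)
from .core import NOISE as NOISE_LABEL
from .classifier import label_reference_segment

#: 10-second windows per hour; converts hours to effective trial counts.
WINDOWS_PER_HOUR = 3600.0 / SEGMENT_S


# ---------------------------------------------------------------------------
# Duration confusion matrix
# ---------------------------------------------------------------------------

@dataclass
class DurationConfusion:
    """Hours-valued predicted x reference confusion matrix.

    Rows: predicted classes (AF/AFL, non-AF/AFL, noninterpretable).
    Columns: reference classes (AF, AFL, non-AF/AFL, noninterpretable).
    """

    hours: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.hours.reindex(index=PRED_CLASSES, columns=REF_CLASSES)
        if df.isna().any().any():
            raise ValueError(
                f"confusion matrix needs rows {PRED_CLASSES} and columns {REF_CLASSES}"
            )
        if (df.values < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")
        self.hours = df.astype(float)

    @classmethod
    def from_array(cls, matrix) -> "DurationConfusion":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 4):
            raise ValueError(f"expected a 3x4 hours matrix, got shape {m.shape}")
        return cls(pd.DataFrame(m, index=PRED_CLASSES, columns=REF_CLASSES))

    @property
    def total_h(self) -> float:
        return float(self.hours.values.sum())

    def pooled_3x3(self) -> pd.DataFrame:
        """Pool AF and AFL reference columns into one AF/AFL class."""
        df = self.hours
        return pd.DataFrame(
            {AFIB_FLUTTER: df[AF] + df[AFL], NON_AF: df[NON_AF],
             UNINTERPRETABLE: df[UNINTERPRETABLE]},
            index=PRED_CLASSES)

    def __add__(self, other: "DurationConfusion") -> "DurationConfusion":
        return DurationConfusion(self.hours + other.hours)


def time_confusion(post_labels: Mapping[str, Sequence[SegmentLabel]],
                   references: Mapping[str, RhythmTimeline]) -> DurationConfusion:
    """Tally every classified window against its reference class.

    Each window contributes ``SEGMENT_S/3600`` hours to exactly one cell.
    Patients present in ``post_labels`` must have a reference timeline
    covering their windows.
    """
    hours = pd.DataFrame(0.0, index=PRED_CLASSES, columns=REF_CLASSES)
    for pid, labels in post_labels.items():
        if pid not in references:
            raise ValueError(f"no reference timeline for patient {pid}")
        ref = references[pid]
        for lab in labels:
            ref_class = label_reference_segment(ref, lab.t_start_s, lab.t_end_s)
            hours.loc[lab.label, ref_class] += (lab.t_end_s - lab.t_start_s) / 3600.0
    return DurationConfusion(hours)


# ---------------------------------------------------------------------------
# Proportion metrics with Wilson CIs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricWithCI:
    """A proportion or index with an optional confidence interval."""

    estimate: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: str = "none"
    numerator_h: Optional[float] = None
    denominator_h: Optional[float] = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)

    @property
    def pct(self) -> float:
        return 100.0 * self.estimate


_UNDEFINED = MetricWithCI(float("nan"), method="undefined")


def wilson_ci(successes: float, trials: float,
              level: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level,
                                method="wilson")
    return float(lo), float(hi)


def _hours_metric(num_h: float, den_h: float) -> MetricWithCI:
    if den_h <= 0:
        return _UNDEFINED
    est = num_h / den_h
    # Wilson CI on effective 10-s window counts behind the hour totals.
    n = den_h * WINDOWS_PER_HOUR
    lo, hi = wilson_ci(est * n, n)
    return MetricWithCI(est, lo, hi, "wilson", num_h, den_h)


def one_vs_rest_metrics(conf: DurationConfusion,
                        positive_class: str = AFIB_FLUTTER) -> Dict[str, MetricWithCI]:
    """Time-based one-vs-rest metrics for one predicted class.

    For the AF/AFL class, reference positives are the AF and AFL columns
    pooled; the result additionally carries AF-only and AFL-only
    sensitivities.  Sensitivity, specificity, PPV and NPV are ratios of
    hours with Wilson CIs; F1 is the harmonic mean of PPV and
    sensitivity; accuracy is the three-class diagonal share.
    """
    if positive_class not in PRED_CLASSES:
        raise ValueError(f"positive_class must be one of {PRED_CLASSES}")
    df = conf.hours
    pos_cols = {AFIB_FLUTTER: [AF, AFL], NON_AF: [NON_AF],
                UNINTERPRETABLE: [UNINTERPRETABLE]}[positive_class]
    neg_cols = [c for c in REF_CLASSES if c not in pos_cols]
    tp = float(df.loc[positive_class, pos_cols].sum())
    fn = float(df.loc[[r for r in PRED_CLASSES if r != positive_class],
                      pos_cols].values.sum())
    fp = float(df.loc[positive_class, neg_cols].sum())
    tn = float(df.loc[[r for r in PRED_CLASSES if r != positive_class],
                      neg_cols].values.sum())

    out = {
        "sensitivity": _hours_metric(tp, tp + fn),
        "specificity": _hours_metric(tn, tn + fp),
        "ppv": _hours_metric(tp, tp + fp),
        "npv": _hours_metric(tn, tn + fn),
    }
    sens, ppv = out["sensitivity"], out["ppv"]
    if sens.defined and ppv.defined and (sens.estimate + ppv.estimate) > 0:
        f1 = 2 * ppv.estimate * sens.estimate / (ppv.estimate + sens.estimate)
        out["f1"] = MetricWithCI(f1, method="none")
    else:
        out["f1"] = _UNDEFINED
    pooled = conf.pooled_3x3()
    out["accuracy"] = _hours_metric(float(np.trace(pooled.values)), conf.total_h)
    if positive_class == AFIB_FLUTTER:
        out["sensitivity_af"] = _hours_metric(
            float(df.loc[AFIB_FLUTTER, AF]), float(df[AF].sum()))
        out["sensitivity_afl"] = _hours_metric(
            float(df.loc[AFIB_FLUTTER, AFL]), float(df[AFL].sum()))
    return out


def bootstrap_f1_ci(patient_confusions: Mapping[str, DurationConfusion],
                    positive_class: str = AFIB_FLUTTER, B: int = 2000,
                    rng: Optional[np.random.Generator] = None,
                    level: float = 0.95) -> Tuple[float, float]:
    """Percentile bootstrap CI for the pooled F1, resampling patients.

    Patients are drawn with replacement ``B`` times; each draw pools the
    resampled per-patient hour matrices and recomputes F1.  Degenerate
    draws with undefined F1 are redrawn (their count is discarded after
    a safety cap).  Deterministic for a seeded generator.
    """
    if len(patient_confusions) < 2:
        raise ValueError("bootstrap requires at least 2 patients")
    rng = rng if rng is not None else np.random.default_rng(0)
    pids = sorted(patient_confusions)
    mats = np.stack([patient_confusions[p].hours.values for p in pids])
    stats: List[float] = []
    attempts = 0
    while len(stats) < B:
        attempts += 1
        if attempts > 20 * B:
            raise RuntimeError("too many degenerate bootstrap draws")
        idx = rng.integers(0, len(pids), size=len(pids))
        pooled = DurationConfusion.from_array(mats[idx].sum(axis=0))
        f1 = one_vs_rest_metrics(pooled, positive_class)["f1"]
        if f1.defined:
            stats.append(f1.estimate)
    a = 100 * (1 - level) / 2
    lo, hi = np.percentile(stats, [a, 100 - a])
    return float(lo), float(hi)


def cohen_kappa(conf: DurationConfusion) -> float:
    """Duration-weighted Cohen kappa on the pooled 3x3 matrix."""
    p = conf.pooled_3x3().values
    n = p.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(p) / n
    pe = float(p.sum(axis=1) @ p.sum(axis=0)) / n ** 2
    if abs(1 - pe) < 1e-12:
        return float("nan")
    return float((po - pe) / (1 - pe))


# ---------------------------------------------------------------------------
# Episode-based (patient-level) detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpisodeConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


def _count_metric(successes: int, trials: int) -> MetricWithCI:
    if trials <= 0:
        return _UNDEFINED
    lo, hi = wilson_ci(successes, trials)
    return MetricWithCI(successes / trials, lo, hi, "wilson",
                        float(successes), float(trials))


def episode_metrics(conf: EpisodeConfusion) -> Dict[str, MetricWithCI]:
    """Sensitivity/specificity/PPV/NPV with Wilson CIs, plus Youden J."""
    out = {
        "sensitivity": _count_metric(conf.tp, conf.tp + conf.fn),
        "specificity": _count_metric(conf.tn, conf.tn + conf.fp),
        "ppv": _count_metric(conf.tp, conf.tp + conf.fp),
        "npv": _count_metric(conf.tn, conf.tn + conf.fn),
    }
    sens, spec = out["sensitivity"], out["specificity"]
    j = (sens.estimate + spec.estimate - 1.0
         if sens.defined and spec.defined else float("nan"))
    out["youden"] = MetricWithCI(j, method="none")
    return out


def episode_detection(cohort: Sequence[tuple]) -> Tuple[EpisodeConfusion,
                                                        Dict[str, MetricWithCI],
                                                        Dict[str, MetricWithCI]]:
    """Patient-level AF/AFL detection over a cohort.

    ``cohort`` holds ``(reference_timeline, post_labels, index_arrhythmia)``
    per patient.  Each patient contributes one positive unit per
    reference-confirmed AF/AFL period — a true positive when at least one
    postprocessed AF/AFL window falls inside it — and one negative unit
    per reference SR period, a false positive when any AF/AFL window
    falls inside that.  Returns the 2x2 confusion, its metrics, and
    AF-only / AFL-only episode sensitivities keyed ``sensitivity_af`` /
    ``sensitivity_afl``.
    """
    tp = fp = fn = tn = 0
    by_type = {AF: [0, 0], AFL: [0, 0]}  # detected, total
    for reference, post_labels, index_lab in cohort:
        # one unit per continuous rhythm period; noninterpretable stretches
        # inside a period do not split it
        periods: List[List] = []
        for s, e, lab in reference.intervals:
            if lab == NOISE_LABEL:
                continue
            kind = "AFAFL" if lab in (AF, AFL) else SR
            if periods and periods[-1][2] == kind:
                periods[-1][1] = e
            else:
                periods.append([s, e, kind])
        af_periods = [(s, e) for s, e, k in periods if k == "AFAFL"]
        sr_periods = [(s, e) for s, e, k in periods if k == SR]
        if not af_periods and not sr_periods:
            continue  # no reference periods: excluded
        def _hit(span):
            # only windows fully inside the period count, so a window
            # straddling a rhythm transition cannot flag the wrong period
            s, e = span
            return any(l.label == AFIB_FLUTTER
                       and l.t_start_s >= s - 1e-9 and l.t_end_s <= e + 1e-9
                       for l in post_labels)
        for span in af_periods:
            if _hit(span):
                tp += 1
                by_type[index_lab][0] += 1
            else:
                fn += 1
            by_type[index_lab][1] += 1
        for span in sr_periods:
            if _hit(span):
                fp += 1
            else:
                tn += 1
    conf = EpisodeConfusion(tp, fp, fn, tn)
    extra = {
        "sensitivity_af": _count_metric(*by_type[AF]),
        "sensitivity_afl": _count_metric(*by_type[AFL]),
    }
    return conf, episode_metrics(conf), extra


# ---------------------------------------------------------------------------
# Burden agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman bias and 95% limits of agreement (hours)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def bland_altman(predicted: Sequence[float],
                 reference: Sequence[float]) -> AgreementResult:
    """Mean difference (predicted - reference) and bias +/- 1.96 SD."""
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape or pred.size < 2:
        raise ValueError("need at least 2 equal-length pairs")
    d = pred - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, d.size)


@dataclass(frozen=True)
class ICCResult:
    """Single-measurement ICC (absolute agreement) with CI and p-value.

    ``icc_consistency`` is the consistency variant of the same two-way
    decomposition, reported alongside for reference.
    """

    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    icc_consistency: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.icc)


def icc_single_rater(predicted: Sequence[float],
                     reference: Sequence[float]) -> ICCResult:
    """ICC between two measurement methods on the same subjects.

    Two-way model, absolute agreement, single measurements — the form
    appropriate when the two raters (here: automated pipeline and
    physician reference) are the raters of interest and single values are
    compared.  The F-based CI and p-value follow the standard two-way
    ANOVA decomposition.
    """
    import pingouin as pg

    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape or pred.size < 3:
        raise ValueError("need at least 3 equal-length pairs")
    if np.var(np.concatenate([pred, ref])) == 0 or np.var(0.5 * (pred + ref)) == 0:
        return ICCResult(float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"))
    n = pred.size
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["pred", "ref"], n),
        "value": np.concatenate([pred, ref]),
    })
    res = pg.intraclass_corr(data=df, targets="subject", raters="rater",
                             ratings="value")
    res = res.set_index(res["Type"].str.replace(r"[()]", "", regex=True)
                        .str.replace(",", ""))
    # row labels vary across pingouin versions: ICC(A,1)/ICC(C,1) or ICC2/ICC3
    abs_key = "ICCA1" if "ICCA1" in res.index else "ICC2"
    con_key = "ICCC1" if "ICCC1" in res.index else "ICC3"
    row = res.loc[abs_key]   # single measurements, absolute agreement
    row3 = res.loc[con_key]  # consistency variant
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(float(row["ICC"]), float(lo), float(hi),
                     float(row["pval"]), float(row3["ICC"]))


# ---------------------------------------------------------------------------
# CHA2DS2-VA stroke-risk score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientCovariates:
    age: float
    chf: bool = False
    hypertension: bool = False
    diabetes: bool = False
    stroke_tia: bool = False
    vascular_disease: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")


def cha2ds2va(cov: PatientCovariates) -> int:
    """CHA2DS2-VA score: 2 points for age >= 75 or prior stroke/TIA,
    1 point each for age 65-74, heart failure, hypertension, diabetes and
    vascular disease (age bands mutually exclusive)."""
    score = 0
    if cov.age >= 75:
        score += 2
    elif cov.age >= 65:
        score += 1
    score += 2 * cov.stroke_tia
    score += cov.chf + cov.hypertension + cov.diabetes + cov.vascular_disease
    return int(score)
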