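"""End-to-end pipeline: simulate -> classify -> postprocess -> evaluate.

Also hosts the evaluation-report builder used both by the CLI and by
library callers: given per-patient postprocessed labels and reference
timelines it assembles the duration confusion matrix, one-vs-rest
metrics with CIs, kappa, episode-level detection, burden agreement
(Bland-Altman + ICC) and the rhythm-change delay summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import io as aio
from .classifier import classify_record, label_reference_segment
from .core import AF, AFL, AFIB_FLUTTER, NON_AF, SR, RhythmTimeline
from .episodes import (BurdenRecord, DelayRecord, build_episodes,
                       compute_burden, detection_delay, postprocessed_labels)
from .metrics import (DurationConfusion, bland_altman, cohen_kappa,
                      episode_detection, icc_single_rater, one_vs_rest_metrics,
                      time_confusion)
from .synthio import PatientSim, simulate_cohort

log = logging.getLogger("afstrap")


def process_patient(sim: PatientSim, classifier_params=None,
                    postprocess_params=None) -> dict:
    """Run classification + postprocessing for one simulated patient."""
    raw = classify_record(sim.record, classifier_params)
    eps = build_episodes(raw, postprocess_params)
    post = postprocessed_labels(raw, eps)
    ref_durs = sim.reference.durations_by_label()
    return {
        "raw_labels": raw,
        "episodes": eps,
        "post_labels": post,
        "burden": BurdenRecord(
            patient_id=sim.patient_id,
            predicted_burden_h=compute_burden(eps, sim.record.duration_s),
            reference_burden_h=(ref_durs.get(AF, 0.0) + ref_durs.get(AFL, 0.0))
            / 3600.0),
    }


def evaluate_cohort(post_labels: Dict[str, Sequence],
                    references: Dict[str, RhythmTimeline],
                    burdens: Sequence[BurdenRecord],
                    delays: Sequence[DelayRecord],
                    index_arrhythmia: Optional[Dict[str, str]] = None) -> dict:
    """Assemble every cohort-level statistic into one plain dict."""
    conf = time_confusion(post_labels, references)
    ovr = one_vs_rest_metrics(conf, AFIB_FLUTTER)
    kappa = cohen_kappa(conf)
    cohort = [(references[pid], post_labels[pid],
               (index_arrhythmia or {}).get(pid, AF))
              for pid in sorted(post_labels)]
    econf, emetrics, etype = episode_detection(cohort)
    pred = [b.predicted_burden_h for b in burdens]
    ref = [b.reference_burden_h for b in burdens]
    agree = bland_altman(pred, ref) if len(pred) >= 2 else None
    icc = icc_single_rater(pred, ref) if len(pred) >= 3 else None
    ok_delays = [d.delay_s for d in delays if not d.missing]
    return {
        "confusion_hours": conf.hours,
        "time_metrics": ovr,
        "kappa": kappa,
        "episode_confusion": econf,
        "episode_metrics": emetrics,
        "episode_metrics_by_type": etype,
        "bland_altman": agree,
        "icc": icc,
        "delays_s": ok_delays,
        "n_missing_delays": sum(d.missing for d in delays),
    }


def report_text(results: dict) -> str:
    """Human-readable evaluation report; hours printed to 0.1 precision."""
    lines: List[str] = []
    conf = results["confusion_hours"]
    lines.append("Duration confusion matrix (hours)")
    lines.append(conf.round(1).to_string())
    lines.append("")
    lines.append("Time-based one-vs-rest metrics, positive class AF/AFL")
    for name, m in results["time_metrics"].items():
        if not m.defined:
            lines.append(f"  {name}: undefined")
        elif m.method == "wilson":
            lines.append(f"  {name}: {m.pct:.1f}% "
                         f"({m.numerator_h:.1f}/{m.denominator_h:.1f} h, "
                         f"95% CI {100 * m.ci_low:.1f}-{100 * m.ci_high:.1f})")
        else:
            lines.append(f"  {name}: {m.estimate:.2f}")
    lines.append(f"  cohen_kappa: {results['kappa']:.2f}")
    econf = results["episode_confusion"]
    lines.append("")
    lines.append(f"Episode detection: TP {econf.tp}  FP {econf.fp}  "
                 f"FN {econf.fn}  TN {econf.tn}")
    for name, m in results["episode_metrics"].items():
        if m.method == "wilson":
            lines.append(f"  {name}: {m.pct:.1f}% "
                         f"(95% CI {100 * m.ci_low:.1f}-{100 * m.ci_high:.1f})")
        elif m.defined:
            lines.append(f"  {name}: {m.estimate:.2f}")
    ba, icc = results["bland_altman"], results["icc"]
    if ba is not None:
        lines.append("")
        lines.append(f"Burden agreement: bias {ba.bias:.2f} h, "
                     f"LoA {ba.loa_low:.2f} to {ba.loa_high:.2f} h (n={ba.n})")
    if icc is not None and icc.defined:
        lines.append(f"  ICC (absolute agreement, single): {icc.icc:.2f} "
                     f"(95% CI {icc.ci_low:.2f}-{icc.ci_high:.2f}, "
                     f"p={icc.p_value:.2g})")
    delays = results["delays_s"]
    if delays:
        lines.append("")
        lines.append(f"AF/AFL-to-SR delay: median {np.median(delays):.1f} s "
                     f"over {len(delays)} transitions "
                     f"({results['n_missing_delays']} undetected)")
    return "\n".join(lines) + "\n"


def run_pipeline(config: "aio.RunConfig", out_dir,
                 write_waveforms: bool = False) -> Path:
    """Simulate a cohort, classify, postprocess, evaluate; write artifacts.

    Deterministic: identical config (including seed) produces
    byte-identical artifacts.  Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim
    log.info("simulating cohort: n=%d seed=%d", sim_cfg.n_patients, sim_cfg.seed)
    cohort = simulate_cohort(sim_cfg)

    aio.write_timelines({p.patient_id: p.truth for p in cohort},
                        out / "truth_timelines.csv")
    aio.write_timelines({p.patient_id: p.reference for p in cohort},
                        out / "reference_timelines.csv")
    if write_waveforms:
        for p in cohort:
            aio.write_record(p.record, out / f"record_{p.patient_id}.csv")

    post_labels, burdens, delays, raw_labels, all_eps = {}, [], [], {}, []
    index_arr = {}
    for p in cohort:
        r = process_patient(p, config.classifier, config.postprocess)
        raw_labels[p.patient_id] = r["raw_labels"]
        post_labels[p.patient_id] = r["post_labels"]
        burdens.append(r["burden"])
        all_eps.extend(r["episodes"])
        index_arr[p.patient_id] = p.index_arrhythmia
        if p.cardioversion_time_s is not None:
            delays.append(detection_delay(p.reference, r["post_labels"]))

    aio.write_labels(raw_labels, out / "labels_raw.csv")
    aio.write_labels(post_labels, out / "labels_post.csv")
    aio.write_episodes(all_eps, out / "episodes.csv")
    aio.write_burden(burdens, out / "burden.csv")
    aio.write_delays(delays, out / "delays.csv")

    results = evaluate_cohort(post_labels,
                              {p.patient_id: p.reference for p in cohort},
                              burdens, delays, index_arr)
    (out / "report.txt").write_text(report_text(results))
    (out / "metrics.json").write_text(_results_json(results))
    log.info("pipeline complete: %s", out)
    return out


def _results_json(results: dict) -> str:
    def metric(m):
        if m is None or not m.defined:
            return None
        d = {"estimate": m.estimate}
        if m.ci_low is not None:
            d.update(ci_low=m.ci_low, ci_high=m.ci_high, method=m.method)
        return d

    econf = results["episode_confusion"]
    ba, icc = results["bland_altman"], results["icc"]
    payload = {
        "confusion_hours": results["confusion_hours"].round(9).to_dict(),
        "time_metrics": {k: metric(m) for k, m in results["time_metrics"].items()},
        "kappa": results["kappa"],
        "episode_confusion": {"tp": econf.tp, "fp": econf.fp,
                              "fn": econf.fn, "tn": econf.tn},
        "episode_metrics": {k: metric(m)
                            for k, m in results["episode_metrics"].items()},
        "bland_altman": None if ba is None else {
            "bias_h": ba.bias, "loa_low_h": ba.loa_low, "loa_high_h": ba.loa_high},
        "icc": None if icc is None or not icc.defined else {
            "icc": icc.icc, "ci_low": icc.ci_low, "ci_high": icc.ci_high,
            "p": icc.p_value},
        "median_delay_s": (float(np.median(results["delays_s"]))
                           if results["delays_s"] else None),
        "n_missing_delays": results["n_missing_delays"],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
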