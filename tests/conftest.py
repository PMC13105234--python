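import numpy as np
import pytest

from afstrap import (AFIB_FLUTTER, NON_AF, SegmentLabel, SimConfig,
                     UNINTERPRETABLE, simulate_cohort)
from afstrap.episodes import detection_delay
from afstrap.pipeline import evaluate_cohort, process_patient

_CHAR_TO_LABEL = {"A": AFIB_FLUTTER, "N": NON_AF, "U": UNINTERPRETABLE}


def labels_from_string(pattern: str, patient_id: str = "P000"):
    """Build a window-label sequence from e.g. 'AAANU' (10 s per char)."""
    return [SegmentLabel(patient_id, i, 10.0 * i, 10.0 * (i + 1),
                         _CHAR_TO_LABEL[c]) for i, c in enumerate(pattern)]


@pytest.fixture(scope="session")
def noisy_cohort5():
    """Small cohort with noise bursts and waveforms, desk-scale durations."""
    return simulate_cohort(SimConfig.scaled(n_patients=5, seed=3))


@pytest.fixture(scope="session")
def clean_cohort_results():
    """50-patient noise-free cohort pushed through the whole pipeline."""
    cfg = SimConfig.scaled(n_patients=50, seed=1, noise_burst_rate_per_hour=0.0)
    cohort = simulate_cohort(cfg)
    post, burdens, delays, idx = {}, [], [], {}
    for p in cohort:
        r = process_patient(p)
        post[p.patient_id] = r["post_labels"]
        burdens.append(r["burden"])
        idx[p.patient_id] = p.index_arrhythmia
        if p.cardioversion_time_s is not None:
            delays.append(detection_delay(p.reference, r["post_labels"]))
    results = evaluate_cohort(post, {p.patient_id: p.reference for p in cohort},
                              burdens, delays, idx)
    return {"cohort": cohort, "post": post, "burdens": burdens,
            "delays": delays, "results": results}
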