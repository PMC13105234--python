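# Methods

`afstrap` re-implements, as a tested library, the analysis workflow behind
wearable single-lead ECG rhythm monitoring in patients with recent-onset
atrial fibrillation (AF) or atrial flutter (AFL) undergoing cardioversion:
10-second segment classification into AF/AFL, non-AF/AFL and
noninterpretable; episode postprocessing; AF/AFL burden and
rhythm-change-delay estimation; and the full diagnostic-accuracy
evaluation. Because neither the clinical recordings nor the trained deep
network behind the original workflow are publicly available, the package
pairs the pipeline with (a) a synthetic cohort generator that emulates the
study design with controllable ground truth and (b) a transparent
rule-based segment classifier fulfilling the same classification contract.

## Study-design model

Each simulated patient is a continuous single-lead chest ECG recording
(256 Hz, µV) that starts in AF — or AFL with probability 17/116 — and,
with probability 109/116, transitions once to sinus rhythm (SR) at a
recorded cardioversion time. Short bursts of motion artifact are
superimposed as NOISE intervals at a Poisson rate. The ground-truth
timeline is a contiguous tiling of half-open intervals labelled
AF/AFL/SR/NOISE; the physician-style reference annotation is derived from
it by the 10-second rule: noise periods of at least 10 s stay
noninterpretable, shorter ones are absorbed into the surrounding rhythm.
When a short burst is flanked by different rhythms the preceding label
wins — a deterministic tie rule chosen so the operation is idempotent and
machine-checkable; in practice flanking rhythms are identical.

Default `SimConfig` values mirror the study conditions: 116 patients,
recording durations normal(241.2, 93.6) minutes truncated at 30 minutes,
AF/AFL occupying ~48% of recorded time (the pre-cardioversion fraction is
drawn from normal(0.48, 0.15) clipped to [0.25, 0.75]), and noise bursts
at 6/h with normal(30, 15) s lengths (~5% of time noninterpretable).
Burst duration and clustering are not constrained by published study
values and are exposed as configuration. `SimConfig.scaled()` keeps every
probability and rate but expresses durations in seconds rather than
minutes (mean 241.2 s, SD 93.6 s, floor 120 s); all fixture and
acceptance cohorts use this desk-scale preset so a 50-patient end-to-end
run completes in seconds. The floor of 120 s guarantees both a ≥30 s
arrhythmia phase and a measurable SR phase in every patient.

## Waveform synthesis

Waveforms are template-based, not biophysical: Gaussian P-QRS-T templates
(R 1000 µV, P 120 µV, T 250 µV) on a per-rhythm RR process —
SR: RR with ~3% beat-to-beat noise at 55-85 bpm; AF: i.i.d. lognormal RR
(CV ≈ 0.25) at 95-130 bpm with no P waves and a 4-9 Hz band-limited
fibrillatory baseline (45 µV); AFL: fixed 2:1 conduction of a 300/min
atrial rate (RR ≈ 0.4 s, tiny jitter) plus a 5 Hz sawtooth flutter wave
(250 µV). NOISE intervals carry broadband artifact (900 µV SD) and
baseline wander instead of beats; 6 µV white sensor noise is added
everywhere. This produces exactly known fiducials (beat and P-wave times
are returned by `synthesize_ecg_annotated`) at the cost of realism: no
respiratory modulation, electrode-contact dynamics, PQ/QT adaptation, ectopy,
or gradual signal degradation. Passing tests therefore demonstrate that the
*pipeline machinery* — segmentation, postprocessing, statistics — is
correct, not that the baseline classifier would reach the published
accuracy on clinical recordings.

## Segmentation and classification

Records are polyphase-resampled to 125 Hz, cut into consecutive
non-overlapping 10-s windows aligned to recording start (a trailing
partial window is dropped; no padding), and the single lead is replicated
across 3 channels — the input representation the original network
expects. The baseline classifier is deliberately simple and fully
deterministic:

1. **Quality gate** — a window is noninterpretable if the longest
   near-constant run exceeds 40% of the window, power above 40 Hz exceeds
   25% of the 0.5-40 Hz power, amplitude range falls outside
   [300, 4000] µV, or fewer than 4 R peaks are detected.
2. **R peaks** — 5-30 Hz bandpass, peak threshold at 45% of the window
   maximum, 0.2 s refractory period.
3. **Irregularity** — AF/AFL when both CV(RR) > 0.12 and
   normalized RMSSD of RR > 0.10.
4. **Flutter path** — when RR is near-constant (CV < 0.06), QRS complexes
   are cancelled (±50 ms linear interpolation) and the window is AF/AFL if
   the mean rate lies in 120-165 bpm (2:1 conduction territory) and the
   3.5-6.5 Hz share of 1-10 Hz residual power exceeds 0.35. The decision
   rule itself (`decide_rhythm`) depends only on rate and atrial
   periodicity, so increasing CV(RR) alone can never flip AF/AFL back to
   non-AF/AFL.

Thresholds ship in `ClassifierParams`; on noise-free synthetic cohorts the
baseline exceeds 95% window accuracy against ground truth (an internal
quality bar for the synthetic conditions, not a clinical claim). Reference
window labels use majority overlap with ties to the earlier interval, and
AF/AFL are kept distinct in reference space so arrhythmia-specific
sensitivities stay computable.

## Episode postprocessing, burden, delay

Maximal runs of AF/AFL windows form candidates; candidates separated by
gaps are merged (gap time included) and merged candidates shorter than
30 s are discarded, matching the guideline minimum of 30 s of continuous
single-lead ECG for an AF diagnosis. Merging precedes filtering — the
only order under which closely spaced sub-30-s runs can be rescued into
one episode. The gap rule: purely noninterpretable gaps are bridged
regardless of length (noise inside an episode should not split it);
gaps containing non-AF/AFL windows are bridged only up to `max_gap_s`
(default 30 s, symmetric with the minimum; the published description says
only "short gaps", so the value is configuration with this documented
default). Burden is the summed episode time in hours.

Rhythm-change delay is the time from the start of the first reference SR
interval after the AF/AFL period to the start of the first postprocessed
non-AF/AFL window at or after that onset, with one window of slack for a
window already non-AF/AFL straddling the transition (so delay ≥ −10 s).
Transitions the classifier never confirms are flagged and excluded from
summaries. Only AF/AFL→SR delays are computed, mirroring the
cardioversion study protocol.

## Statistics

* **Duration confusion matrix** — each window contributes 10/3600 h to one
  (predicted, reference) cell; predicted classes × {AF, AFL, non-AF/AFL,
  noninterpretable}.
* **One-vs-rest time-based metrics** — hour ratios; Wilson score CIs
  computed on the 10-s window counts behind the hours (n = hours × 360),
  consistent with the segment-based analysis. Zero denominators flag the
  metric undefined rather than propagating NaN.
* **F1 bootstrap** — patients (not windows) are resampled with
  replacement, 2000 iterations by default, percentile bounds;
  patient-level resampling respects within-patient correlation.
  Degenerate draws with undefined F1 are redrawn.
* **Cohen kappa** — duration-weighted, on the 3×3 matrix after pooling AF
  and AFL reference columns.
* **Episode-level detection** — one positive unit per continuous
  reference AF/AFL period and one negative unit per reference SR period;
  noninterpretable stretches do not split a period. A period is flagged
  when at least one postprocessed AF/AFL window lies fully inside it —
  full containment, so a single window straddling the cardioversion
  cannot count toward the wrong period. Wilson CIs on counts; Youden
  J = sensitivity + specificity − 1.
* **Burden agreement** — Bland-Altman bias with 95% limits of agreement
  (bias ± 1.96 SD of differences, SD with n−1), and the intraclass
  correlation for single measurements with absolute agreement from the
  two-way ANOVA decomposition (computed through `pingouin`, with an
  independent ANOVA oracle in the test suite). The consistency variant is
  reported alongside. The published description of the ICC ("2-way
  mixed-effects, absolute agreement, single measurements") is followed;
  note the "model 3.1" shorthand usually denotes the consistency form —
  the estimator implemented here is the absolute-agreement one the
  description specifies.
* **CHA₂DS₂-VA** — 2 points for age ≥ 75 or prior stroke/TIA; 1 point each
  for age 65-74, heart failure, hypertension, diabetes, vascular disease.

## Numerical conventions and degenerate inputs

Times are seconds from recording start with half-open intervals, making
window arithmetic exact. Timeline construction validates contiguity to
1 ns-scale tolerance. All randomness flows through numpy `Generator`s
spawned per patient from a master `SeedSequence`, so cohorts are
reproducible byte-for-byte and patients are independent of cohort size
ordering. Hours are printed to 0.1 precision in reports; machine-readable
outputs keep full precision. Fewer than 3 RR intervals yield zero
irregularity statistics; fewer than 2 burden pairs reject Bland-Altman,
fewer than 3 reject the ICC; zero between-subject variance flags the ICC
undefined.

## Known limitations

* The rule-based classifier is a contract stand-in, not a re-creation of
  the original residual network; its per-segment accuracy on real
  single-lead recordings is untested and would be lower.
* WFDB input/output is not provided; records travel as CSV (`t_s`, `uV`).
* The simulator does not model SR→AF relapse, multi-episode paroxysmal
  patterns, or rate-control drug effects; the delay metric is AF→SR only.
* Published cohort-level agreement numbers (burden ICC 0.96, bias
  −0.25 h) depend on the clinical recordings and are not reproduction
  targets; the synthetic-recovery tests instead verify the pipeline
  recovers its own ground truth (ICC ≥ 0.9, episode sensitivity 1.0,
  median delay ≤ 20 s on a clean 50-patient cohort).
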