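# afstrap

Rhythm analysis for wearable single-lead chest-strap ECG in atrial
fibrillation (AF) and atrial flutter (AFL): 10-second segment
classification into **AF/AFL**, **non-AF/AFL** and **noninterpretable**,
episode postprocessing (30-s minimum, short-gap merging), AF/AFL burden
and AF→SR rhythm-change-delay estimation, and the complete
diagnostic-accuracy evaluation — duration-weighted confusion matrices,
one-vs-rest metrics with Wilson score intervals, bootstrap F1 intervals,
Cohen kappa, patient-level episode detection with the Youden index,
Bland-Altman agreement, intraclass correlation, and CHA₂DS₂-VA scoring.

The package is aimed at researchers evaluating automated AF detectors
against physician-annotated references. Since clinical recordings from
cardioversion cohorts are rarely shareable, it includes a
seed-deterministic synthetic cohort generator (template-based P-QRS-T
waveforms with ground-truth rhythm timelines emulating a
cardioversion-study design) and a transparent rule-based segment
classifier standing in for a trained neural network; any model exposing
the same segment-classification contract can be plugged in.

## Core quantities

For a recording analysed as consecutive 10-s windows with predicted class
$\hat{y}_i$ and reference class $y_i$, the time-based analysis pools
hours into a confusion matrix $C[\hat{y}, y]$ and reports, e.g.

$$\mathrm{Se} = \frac{C[\text{AF/AFL}, \text{AF}] + C[\text{AF/AFL}, \text{AFL}]}{\sum_{\hat y} C[\hat y,\text{AF}] + C[\hat y, \text{AFL}]}$$

with Wilson 95% CIs on the window counts behind the hours. Episodes are
maximal runs of AF/AFL windows, merged across short gaps and filtered at
30 s; burden is total episode time; the rhythm-change delay is the time
from the reference SR onset after cardioversion to the first
postprocessed non-AF/AFL window. Agreement between estimated and
reference burden uses Bland-Altman bias ± 1.96 SD and ICC (two-way model,
absolute agreement, single measurements).

## Worked example

```python
from afstrap import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(seed=7)
cfg.sim = SimConfig.scaled(n_patients=10, seed=7)   # desk-scale durations
out = run_pipeline(cfg, "demo_out")
print((out / "report.txt").read_text())
```

prints (abridged):

```
Time-based one-vs-rest metrics, positive class AF/AFL
  sensitivity: 100.0% (0.3/0.3 h, 95% CI 96.9-100.0)
  specificity: 96.6% (0.3/0.3 h, 95% CI 91.6-98.7)
  ...
  cohen_kappa: 0.96

Episode detection: TP 10  FP 0  FN 0  TN 10
  sensitivity: 100.0% (95% CI 72.2-100.0)
  ...
  youden: 1.00

Burden agreement: bias 0.00 h, LoA -0.00 to 0.00 h (n=10)
  ICC (absolute agreement, single): 0.99 (95% CI 0.61-1.00, p=5.4e-13)

AF/AFL-to-SR delay: median 3.9 s over 10 transitions (0 undetected)
```

All ten simulated patients' arrhythmia periods are detected, the
estimated AF/AFL burden agrees with ground truth (near-zero bias,
ICC 0.99), and sinus rhythm is recognised a median 3.9 s after the true
rhythm change — the windowing quantizes detection to 10-s steps.

The same statistics can be computed directly from published summary
data, e.g. feeding an hours-valued confusion matrix to
`one_vs_rest_metrics` or episode counts to `episode_metrics`:

```python
from afstrap import DurationConfusion, one_vs_rest_metrics
conf = DurationConfusion.from_array([[191.5, 13.4, 0.06, 1.0],
                                     [2.6, 10.2, 214.1, 1.9],
                                     [4.9, 0.4, 4.8, 21.6]])
m = one_vs_rest_metrics(conf)
print(f"{m['sensitivity'].pct:.1f}")   # 91.9
```

A `afstrap` console command exposes the stages individually
(`simulate | classify | postprocess | evaluate | report | run`).

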