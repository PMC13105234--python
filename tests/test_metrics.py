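"""Statistics: confusion tallies, Wilson CIs, kappa, bootstrap, agreement."""

import numpy as np
import pandas as pd
import pytest

from afstrap import (AF, AFL, AFIB_FLUTTER, DurationConfusion,
                     EpisodeConfusion, NON_AF, PatientCovariates,
                     RhythmTimeline, SR, UNINTERPRETABLE, bland_altman,
                     bootstrap_f1_ci, cha2ds2va, cohen_kappa,
                     episode_detection, episode_metrics, icc_single_rater,
                     one_vs_rest_metrics, time_confusion, wilson_ci)
from afstrap.core import PRED_CLASSES, REF_CLASSES
from conftest import labels_from_string


def _anova_icc_oracle(pred, ref):
    """Independent two-way ANOVA decomposition for n subjects x 2 raters."""
    x = np.column_stack([pred, ref]).astype(float)
    n, k = x.shape
    grand = x.mean()
    ms_rows = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand
    ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
    icc_abs = (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err))
    icc_con = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return icc_abs, icc_con


class TestTimeConfusion:
    def test_random_allocation_matches_brute_force_tally(self):
        rng = np.random.default_rng(2)
        ref = RhythmTimeline([(0, 300, AF), (300, 600, SR)])
        labels = labels_from_string(
            "".join(rng.choice(list("ANU"), size=60)))
        conf = time_confusion({"P000": labels}, {"P000": ref})
        # brute-force tally
        expect = pd.DataFrame(0.0, index=PRED_CLASSES, columns=REF_CLASSES)
        for l in labels:
            col = AF if l.t_start_s < 300 else NON_AF
            expect.loc[l.label, col] += 10 / 3600
        assert np.allclose(conf.hours.values, expect.values)
        assert conf.total_h == pytest.approx(60 * 10 / 3600)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="no reference"):
            time_confusion({"P9": labels_from_string("A")}, {})

    def test_window_beyond_reference_rejected(self):
        ref = RhythmTimeline([(0, 30, AF)])
        with pytest.raises(ValueError):
            time_confusion({"P000": labels_from_string("AAAA")}, {"P000": ref})


class TestOneVsRest:
    def test_perfect_matrix_all_ones(self):
        m = np.zeros((3, 4))
        m[0, 0], m[0, 1] = 2.0, 1.0
        m[1, 2], m[2, 3] = 3.0, 0.5
        out = one_vs_rest_metrics(DurationConfusion.from_array(m))
        for k in ("sensitivity", "specificity", "ppv", "npv", "f1", "accuracy"):
            assert out[k].estimate == pytest.approx(1.0)

    def test_sensitivity_complements_misclassified_hours(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.uniform(0, 5, size=(3, 4))
            conf = DurationConfusion.from_array(m)
            out = one_vs_rest_metrics(conf)
            pos = m[:, 0].sum() + m[:, 1].sum()
            missed = m[1:, 0].sum() + m[1:, 1].sum()
            assert out["sensitivity"].estimate == pytest.approx(1 - missed / pos)

    def test_zero_denominator_flagged(self):
        m = np.zeros((3, 4))
        m[1, 2] = 1.0
        out = one_vs_rest_metrics(DurationConfusion.from_array(m))
        assert not out["sensitivity"].defined
        assert not out["ppv"].defined


class TestWilson:
    def test_matches_closed_form(self):
        z = 1.959963984540054
        for s, n in [(8, 10), (113, 116), (1, 50)]:
            lo, hi = wilson_ci(s, n)
            p = s / n
            center = (p + z * z / (2 * n)) / (1 + z * z / n)
            half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / (1 + z * z / n)
            assert lo == pytest.approx(center - half, abs=1e-12)
            assert hi == pytest.approx(center + half, abs=1e-12)

    @pytest.mark.parametrize("n", [1000, 1_000_000])
    def test_contains_estimate_and_collapses(self, n):
        s = int(0.3 * n)
        lo, hi = wilson_ci(s, n)
        assert lo <= s / n <= hi
        assert (hi - lo) < 0.06 if n == 1000 else (hi - lo) < 0.002

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestKappa:
    def test_diagonal_matrix_kappa_one(self):
        m = np.zeros((3, 4))
        m[0, 0], m[0, 1], m[1, 2], m[2, 3] = 5, 1, 4, 2
        assert cohen_kappa(DurationConfusion.from_array(m)) == pytest.approx(1.0)

    def test_independent_margins_kappa_zero(self):
        # rows proportional to column marginals -> observed = expected
        u = np.array([0.5, 0.3, 0.2])
        v = np.array([0.4, 0.1, 0.3, 0.2])
        m = np.outer(u, v) * 100
        # pool AF+AFL columns coherently: outer structure survives pooling
        assert cohen_kappa(DurationConfusion.from_array(m)) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 3, (3, 4))
        k1 = cohen_kappa(DurationConfusion.from_array(m))
        k2 = cohen_kappa(DurationConfusion.from_array(7.3 * m))
        assert k1 == pytest.approx(k2)


class TestBootstrapF1:
    @staticmethod
    def _patient(hours_correct_af, hours_fp, hours_fn, hours_tn):
        m = np.zeros((3, 4))
        m[0, 0] = hours_correct_af
        m[0, 2] = hours_fp
        m[1, 0] = hours_fn
        m[1, 2] = hours_tn
        return DurationConfusion.from_array(m)

    def test_perfect_cohort_degenerate_interval(self):
        pats = {f"P{i}": self._patient(2.0, 0, 0, 3.0) for i in range(4)}
        lo, hi = bootstrap_f1_ci(pats, B=200, rng=np.random.default_rng(0))
        assert (lo, hi) == (1.0, 1.0)

    def test_seed_determinism(self):
        rng_mats = np.random.default_rng(5)
        pats = {f"P{i}": DurationConfusion.from_array(rng_mats.uniform(0, 2, (3, 4)))
                for i in range(6)}
        a = bootstrap_f1_ci(pats, B=300, rng=np.random.default_rng(7))
        b = bootstrap_f1_ci(pats, B=300, rng=np.random.default_rng(7))
        assert a == b

    def test_two_patient_exhaustive_oracle(self):
        pats = {"P0": self._patient(1.0, 0.5, 0.2, 2.0),
                "P1": self._patient(0.4, 0.1, 0.6, 1.5)}
        # enumerate all 2^2 equally likely resamples
        f1s = []
        for pair in [("P0", "P0"), ("P0", "P1"), ("P1", "P0"), ("P1", "P1")]:
            pooled = DurationConfusion(pats[pair[0]].hours + pats[pair[1]].hours)
            f1s.append(one_vs_rest_metrics(pooled)["f1"].estimate)
        lo, hi = bootstrap_f1_ci(pats, B=500, rng=np.random.default_rng(1))
        assert min(f1s) <= lo <= hi <= max(f1s)
        pooled_f1 = one_vs_rest_metrics(
            DurationConfusion(pats["P0"].hours + pats["P1"].hours))["f1"].estimate
        assert lo <= pooled_f1 <= hi

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_f1_ci({"P0": self._patient(1, 0, 0, 1)})


class TestEpisodeDetection:
    def test_metrics_from_counts(self):
        out = episode_metrics(EpisodeConfusion(tp=113, fp=2, fn=3, tn=107))
        assert round(out["sensitivity"].pct, 1) == 97.4
        assert round(out["specificity"].pct, 1) == 98.2
        assert round(out["youden"].estimate, 2) == 0.96

    def test_youden_complementary_rates(self):
        # sensitivity 0.7 and specificity 0.3 cancel to J = 0
        out = episode_metrics(EpisodeConfusion(tp=7, fp=7, fn=3, tn=3))
        assert out["youden"].estimate == pytest.approx(0.0)

    def test_cohort_counting_with_noise_split_periods(self):
        ref = RhythmTimeline([(0, 100, AF), (100, 115, "NOISE"),
                              (115, 200, AF), (200, 400, SR)])
        hit = labels_from_string("AAA" + "N" * 37)
        miss = labels_from_string("N" * 40)
        conf, out, extra = episode_detection([(ref, hit, AF), (ref, miss, AF)])
        # noise does not split the AF period: one positive unit per patient
        assert (conf.tp, conf.fn, conf.fp, conf.tn) == (1, 1, 0, 2)
        assert extra["sensitivity_af"].estimate == pytest.approx(0.5)


class TestAgreement:
    def test_bland_altman_cases(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.bias, r.loa_low, r.loa_high) == (0.0, 0.0, 0.0)
        r = bland_altman([0.75, 1.75, 2.75], [1.0, 2.0, 3.0])
        assert r.bias == pytest.approx(-0.25)
        assert r.loa_low == pytest.approx(-0.25)
        r = bland_altman([0.0, 2.0, 4.0], [1.0, 2.0, 3.0])  # diffs -1, 0, +1
        assert r.bias == pytest.approx(0.0)
        assert r.loa_high == pytest.approx(1.96)

    def test_icc_perfect_agreement(self):
        vals = [1.0, 5.0, 9.0, 2.5, 7.0]
        r = icc_single_rater(vals, vals)
        assert r.icc == pytest.approx(1.0, abs=1e-6)

    def test_icc_matches_anova_oracle(self):
        pred = [1.0, 2.0, 3.0, 4.0]
        ref = [2.0, 3.0, 4.0, 5.0]
        r = icc_single_rater(pred, ref)
        icc_abs, icc_con = _anova_icc_oracle(pred, ref)
        assert r.icc == pytest.approx(icc_abs, abs=1e-9)
        assert r.icc_consistency == pytest.approx(icc_con, abs=1e-9)
        assert r.icc < r.icc_consistency  # constant shift penalised only by A,1

    def test_icc_one_rater_constant_matches_oracle(self):
        pred = [2.0, 2.0, 2.0, 2.0, 2.0]
        ref = [1.0, 3.0, 5.0, 2.0, 4.0]
        r = icc_single_rater(pred, ref)
        icc_abs, _ = _anova_icc_oracle(pred, ref)
        assert r.icc == pytest.approx(icc_abs, abs=1e-9)
        assert r.icc <= 0.0

    def test_icc_degenerate_flagged(self):
        r = icc_single_rater([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert not r.defined


class TestCha2ds2va:
    @pytest.mark.parametrize("cov,expected", [
        (PatientCovariates(age=40), 0),
        (PatientCovariates(age=70, hypertension=True), 2),
        (PatientCovariates(age=80, stroke_tia=True), 4),
        (PatientCovariates(age=65), 1),
        (PatientCovariates(age=75), 2),
        (PatientCovariates(age=66, chf=True, diabetes=True,
                           vascular_disease=True, hypertension=True), 5),
    ])
    def test_scoring(self, cov, expected):
        assert cha2ds2va(cov) == expected
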