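"""Episode postprocessing, burden arithmetic, and detection delay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afstrap import (AF, AFIB_FLUTTER, NON_AF, PostprocessParams,
                     RhythmTimeline, SR, UNINTERPRETABLE, build_episodes,
                     compute_burden, detection_delay, postprocessed_labels)
from conftest import labels_from_string


def brute_force_episode_seconds(pattern: str, min_windows: int = 3) -> float:
    """Independent run-length oracle: total time of AF runs of at least
    ``min_windows`` consecutive windows (no gap merging)."""
    total = run = 0
    for c in pattern + "$":
        if c == "A":
            run += 1
        else:
            if run >= min_windows:
                total += run
            run = 0
    return 10.0 * total


class TestBuildEpisodes:
    def test_two_windows_excluded(self):
        assert build_episodes(labels_from_string("AANNN")) == []

    def test_three_windows_form_episode(self):
        eps = build_episodes(labels_from_string("AAANN"))
        assert len(eps) == 1
        assert (eps[0].t_start_s, eps[0].t_end_s) == (0.0, 30.0)

    def test_gap_merging_rescues_short_runs(self):
        # 3 AF + 1 non-AF gap + 3 AF -> one merged 70 s episode
        eps = build_episodes(labels_from_string("AAANAAA"))
        assert len(eps) == 1
        assert eps[0].duration_s == pytest.approx(70.0)

    def test_merge_happens_before_filter(self):
        # two 20-s runs with a 10-s gap survive only if merged first
        eps = build_episodes(labels_from_string("AANAA"))
        assert len(eps) == 1
        assert eps[0].duration_s == pytest.approx(50.0)

    def test_long_noninterpretable_gap_bridged(self):
        # 40 s of noninterpretable inside AF does not split the episode
        eps = build_episodes(labels_from_string("AAAUUUUAAA"))
        assert len(eps) == 1
        assert eps[0].duration_s == pytest.approx(100.0)

    def test_long_mixed_gap_not_bridged(self):
        eps = build_episodes(labels_from_string("AAANNNUAAA"))
        assert len(eps) == 2

    def test_unordered_rejected(self):
        labs = labels_from_string("AAA")
        with pytest.raises(ValueError, match="ordered"):
            build_episodes([labs[2], labs[0], labs[1]])

    def test_zero_gap_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        params = PostprocessParams(max_gap_s=0.0,
                                   bridge_uninterpretable_any_gap=False)
        for _ in range(200):
            pattern = "".join(rng.choice(list("ANU"), size=30))
            eps = build_episodes(labels_from_string(pattern), params)
            assert sum(e.duration_s for e in eps) == pytest.approx(
                brute_force_episode_seconds(pattern))

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="ANU", min_size=1, max_size=40),
           st.sampled_from([0.0, 10.0, 30.0]), st.sampled_from([10.0, 30.0]))
    def test_burden_monotone_in_gap_and_idempotent(self, pattern, gap, gap2):
        labs = labels_from_string(pattern)
        lo, hi = sorted((gap, gap2))
        p_lo = PostprocessParams(max_gap_s=lo)
        p_hi = PostprocessParams(max_gap_s=hi)
        t_lo = sum(e.duration_s for e in build_episodes(labs, p_lo))
        t_hi = sum(e.duration_s for e in build_episodes(labs, p_hi))
        assert t_hi >= t_lo - 1e-9
        # idempotence: rebuilding on postprocessed labels gives same episodes
        eps = build_episodes(labs, p_hi)
        post = postprocessed_labels(labs, eps)
        assert build_episodes(post, p_hi) == eps


class TestPostprocessedLabels:
    def test_isolated_window_reassigned(self):
        labs = labels_from_string("NANNN")
        post = postprocessed_labels(labs, build_episodes(labs))
        assert [l.label for l in post] == [NON_AF] * 5

    def test_bridged_gap_window_becomes_af(self):
        labs = labels_from_string("AAANAAA")
        post = postprocessed_labels(labs, build_episodes(labs))
        assert [l.label for l in post] == [AFIB_FLUTTER] * 7

    def test_uninterpretable_outside_episode_unchanged(self):
        labs = labels_from_string("UUNNN")
        post = postprocessed_labels(labs, build_episodes(labs))
        assert [l.label for l in post] == [UNINTERPRETABLE] * 2 + [NON_AF] * 3


class TestBurden:
    def test_burden_values(self):
        labs = labels_from_string("A" * 360)  # one hour of AF windows
        eps = build_episodes(labs)
        assert compute_burden(eps, 3600.0) == pytest.approx(1.0)
        assert compute_burden([], 3600.0) == 0.0

    def test_burden_sum_of_episodes(self):
        labs = labels_from_string("A" * 180 + "N" * 60 + "A" * 90 + "N" * 30)
        eps = build_episodes(labs, PostprocessParams(max_gap_s=30.0))
        assert compute_burden(eps, 3600.0) == pytest.approx((1800 + 900) / 3600)


class TestDetectionDelay:
    def _reference(self, cv_s=300.0, dur_s=600.0):
        return RhythmTimeline([(0, cv_s, AF), (cv_s, dur_s, SR)])

    def test_exact_detection_zero_delay(self):
        labs = labels_from_string("A" * 30 + "N" * 30)
        d = detection_delay(self._reference(), labs)
        assert d.delay_s == pytest.approx(0.0)

    def test_late_detection_positive_delay(self):
        labs = labels_from_string("A" * 35 + "N" * 25)
        d = detection_delay(self._reference(), labs)
        assert d.delay_s == pytest.approx(50.0)

    def test_never_sr_flagged_missing(self):
        labs = labels_from_string("A" * 60)
        d = detection_delay(self._reference(), labs)
        assert d.missing and d.delay_s is None

    def test_no_transition_rejected(self):
        tl = RhythmTimeline([(0, 600, AF)])
        with pytest.raises(ValueError, match="transition|SR"):
            detection_delay(tl, labels_from_string("A" * 60))

    def test_slack_never_below_one_window(self, clean_cohort_results):
        for d in clean_cohort_results["delays"]:
            if not d.missing:
                assert d.delay_s >= -10.0
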