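"""Timepoint sampling, threshold selection, accuracy and bootstrap CIs."""

from __future__ import annotations

import numpy as np
import pytest

import ordentropy as oe
from ordentropy.core import DataError
from ordentropy.evaluate import TimepointSample, threshold_candidates

RESPONSIVE = {"T1": True, "T2": False, "T3": False, "T4": True}


def make_samples(patient_scores: dict[str, dict[str, float]]):
    """Build TimepointSamples from {patient: {timepoint: score}}."""
    return [
        TimepointSample(pid, tp, RESPONSIVE[tp], score)
        for pid, tps in patient_scores.items()
        for tp, score in tps.items()
    ]


def perfect_cohort(n: int, high=1.0, low=0.0):
    return make_samples({
        f"P{i}": {"T1": high, "T2": low, "T3": low, "T4": high}
        for i in range(n)
    })


class TestSampleTimepoints:
    def _series(self, t0=0.0, t1=500.0):
        t = np.arange(t0, t1 + 1.0)
        return oe.EntropyScoreSeries("P0", "PE", t, t * 0.01)

    def test_target_times_and_labels(self):
        events = oe.EventAnnotations("P0", lor_s=100.0, ror_s=400.0)
        samples = oe.sample_timepoints(self._series(), events)
        by_tp = {s.timepoint: s for s in samples}
        # T1..T4 at 85, 130, 385, 430 s
        assert [by_tp[f"T{i}"].score for i in (1, 2, 3, 4)] == \
            pytest.approx([0.85, 1.30, 3.85, 4.30])
        assert [s.responsive for s in samples] == [True, False, False, True]

    def test_window_at_t1_is_entirely_pre_lor(self):
        """The 30 s block stamped at T1 = LoR - 15 covers
        [LoR - 45, LoR - 15]: no anesthetized-state EEG."""
        lor = 100.0
        t1 = lor - 15.0
        window = (t1 - 30.0, t1)
        assert window[1] <= lor

    def test_exact_grid_match(self):
        events = oe.EventAnnotations("P0", lor_s=115.0, ror_s=300.0)
        samples = oe.sample_timepoints(self._series(), events)
        assert samples[0].score == pytest.approx(1.0)  # exactly t=100 s

    def test_out_of_coverage_names_timepoint(self):
        events = oe.EventAnnotations("P0", lor_s=100.0, ror_s=490.0)
        with pytest.raises(DataError, match="T4"):
            oe.sample_timepoints(self._series(), events)


class TestSelectThreshold:
    def test_perfect_separation_midpoint(self):
        samples = make_samples({
            "A": {"T1": 0.8, "T2": 0.1}, "B": {"T1": 0.9, "T2": 0.2},
        })
        thr = oe.select_threshold(samples)
        assert thr == pytest.approx(0.5)
        assert oe.accuracy(samples, thr) == 1.0

    def test_exchangeable_scores_give_half(self):
        samples = make_samples({
            "A": {"T1": 0.3, "T2": 0.7}, "B": {"T1": 0.7, "T2": 0.3},
        })
        thr = oe.select_threshold(samples)
        assert oe.accuracy(samples, thr) == 0.5

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        samples = make_samples({
            f"P{i}": {"T1": rng.normal(1.0), "T2": rng.normal(0.5)}
            for i in range(20)
        })
        thr = oe.select_threshold(samples)
        scores = np.array([s.score for s in samples])
        best = max(oe.accuracy(samples, c) for c in threshold_candidates(scores))
        assert oe.accuracy(samples, thr) == best
        # smallest maximizing candidate wins
        winners = [c for c in threshold_candidates(scores)
                   if oe.accuracy(samples, c) == best]
        assert thr == min(winners)

    def test_uses_only_lor_timepoints(self):
        """T3/T4 values must not influence the threshold."""
        base = {"A": {"T1": 0.9, "T2": 0.1}, "B": {"T1": 0.8, "T2": 0.2}}
        with_t34 = {p: {**tps, "T3": 5.0, "T4": -5.0}
                    for p, tps in base.items()}
        assert oe.select_threshold(make_samples(base)) == \
            oe.select_threshold(make_samples(with_t34))


class TestAccuracy:
    def test_confusion_formula(self):
        # tp=3, tn=4, fp=2, fn=1 -> (3+4)/10 = 0.7
        samples = (
            [TimepointSample(f"a{i}", "T1", True, 1.0) for i in range(3)]
            + [TimepointSample(f"b{i}", "T2", False, 0.0) for i in range(4)]
            + [TimepointSample(f"c{i}", "T2", False, 1.0) for i in range(2)]
            + [TimepointSample("d0", "T1", True, 0.0)]
        )
        assert oe.accuracy(samples, 0.5) == pytest.approx(0.7)

    def test_all_wrong_is_zero(self):
        samples = make_samples({"A": {"T1": 0.0, "T2": 1.0}})
        assert oe.accuracy(samples, 0.5) == 0.0

    def test_tie_at_threshold_is_negative(self):
        s = [TimepointSample("A", "T1", True, 0.5)]
        assert oe.accuracy(s, 0.5) == 0.0  # score == threshold -> negative


class TestEvaluateContrast:
    def test_perfect_cohort_all_contrasts(self):
        samples = perfect_cohort(6)
        thr = oe.select_threshold(samples)
        for contrast in ("LoR", "RoR", "combined"):
            res = oe.evaluate_contrast(samples, thr, contrast, "PE")
            assert res.accuracy == 1.0
            assert res.n_patients == 6

    def test_combined_pools_all_timepoints(self):
        scores = {
            "A": {"T1": 1.0, "T2": 0.0, "T3": 1.0, "T4": 1.0},  # T3 wrong
            "B": {"T1": 0.0, "T2": 0.0, "T3": 0.0, "T4": 1.0},  # T1 wrong
        }
        samples = make_samples(scores)
        lor = oe.evaluate_contrast(samples, 0.5, "LoR").accuracy
        ror = oe.evaluate_contrast(samples, 0.5, "RoR").accuracy
        combined = oe.evaluate_contrast(samples, 0.5, "combined").accuracy
        assert combined == pytest.approx((lor * 4 + ror * 4) / 8)

    def test_missing_timepoint_rejected(self):
        samples = make_samples({"A": {"T1": 1.0, "T2": 0.0, "T3": 0.0}})
        with pytest.raises(DataError, match="T4"):
            oe.evaluate_contrast(samples, 0.5, "combined")

    def test_label_permutation_drives_accuracy_to_half(self):
        """Random responsiveness labels make the classifier uninformative."""
        rng = np.random.default_rng(0)
        scores = rng.normal(size=400)
        accs = []
        for _ in range(200):
            labels = rng.random(400) < 0.5
            samples = [TimepointSample(f"P{i}", "T1", bool(l), s)
                       for i, (l, s) in enumerate(zip(labels, scores))]
            accs.append(oe.accuracy(samples, float(np.median(scores))))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.01)


class TestBootstrapCI:
    def test_identical_patients_zero_width(self):
        samples = perfect_cohort(5)
        lo, hi = oe.bootstrap_ci(samples, 0.5, "LoR", n_boot=500, seed=1)
        assert lo == hi == 1.0

    def test_seeded_determinism(self):
        samples = make_samples({
            f"P{i}": {"T1": v, "T2": 0.4}
            for i, v in enumerate([0.9, 0.2, 0.8, 0.1, 0.7, 0.85])
        })
        ci1 = oe.bootstrap_ci(samples, 0.5, "LoR", n_boot=2000, seed=7)
        ci2 = oe.bootstrap_ci(samples, 0.5, "LoR", n_boot=2000, seed=7)
        assert ci1 == ci2

    def test_bounds_bracket_point_accuracy(self):
        rng = np.random.default_rng(3)
        samples = make_samples({
            f"P{i}": {"T1": rng.normal(0.8, 0.3), "T2": rng.normal(0.2, 0.3)}
            for i in range(30)
        })
        thr = oe.select_threshold(samples)
        acc = oe.evaluate_contrast(samples, thr, "LoR").accuracy
        lo, hi = oe.bootstrap_ci(samples, thr, "LoR", n_boot=4000, seed=0)
        assert 0.0 <= lo <= acc <= hi <= 1.0

    def test_width_matches_binomial_approximation(self):
        """n=50 patients, each correctly classified with probability 0.7
        (both LoR time points jointly): the percentile CI width is within
        20% of the normal-approximation width 2 * 1.96 * sqrt(p(1-p)/50)."""
        rng = np.random.default_rng(12)
        n, p = 50, 0.7
        correct = rng.random(n) < p
        samples = make_samples({
            f"P{i:02d}": ({"T1": 1.0, "T2": 0.0} if c else {"T1": 0.0, "T2": 1.0})
            for i, c in enumerate(correct)
        })
        p_hat = np.mean(correct)
        lo, hi = oe.bootstrap_ci(samples, 0.5, "LoR", n_boot=10_000, seed=5)
        width = hi - lo
        expected = 2 * 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 0.1  # the draw is on target
        assert width == pytest.approx(expected, rel=0.20)

    def test_invalid_replicate_count(self):
        with pytest.raises(DataError):
            oe.bootstrap_ci(perfect_cohort(3), 0.5, "LoR", n_boot=0)


class TestAccuracyDifference:
    def test_identical_scores_zero_difference(self):
        samples = perfect_cohort(6)
        d, lo, hi = oe.accuracy_difference(samples, samples, 0.5, 0.5, "LoR",
                                           n_boot=500, seed=0)
        assert d == lo == hi == 0.0

    def test_perfect_vs_always_wrong(self):
        good = perfect_cohort(5)
        bad = make_samples({
            f"P{i}": {"T1": 0.0, "T2": 1.0, "T3": 1.0, "T4": 0.0}
            for i in range(5)
        })
        d, lo, hi = oe.accuracy_difference(good, bad, 0.5, 0.5, "combined",
                                           n_boot=500, seed=0)
        assert d == 1.0 and lo == hi == 1.0

    def test_patient_mismatch_rejected(self):
        a = perfect_cohort(4)
        b = make_samples({
            f"Q{i}": {"T1": 1.0, "T2": 0.0, "T3": 0.0, "T4": 1.0}
            for i in range(4)
        })
        with pytest.raises(DataError, match="patient sets differ"):
            oe.accuracy_difference(a, b, 0.5, 0.5, "LoR")

    def test_paired_ci_narrower_than_unpaired_when_correlated(self):
        """When the two scores succeed/fail on the same patients, pairing
        cancels the shared variation and tightens the difference CI."""
        rng = np.random.default_rng(21)
        n = 40
        correct = rng.random(n) < 0.7  # both scores correct on same patients
        extra_wrong = rng.random(n) < 0.1  # B occasionally worse
        scores_a, scores_b = {}, {}
        for i, (c, w) in enumerate(zip(correct, extra_wrong)):
            pid = f"P{i:02d}"
            scores_a[pid] = {"T1": 1.0, "T2": 0.0} if c else {"T1": 0.0, "T2": 1.0}
            cb = c and not w
            scores_b[pid] = {"T1": 1.0, "T2": 0.0} if cb else {"T1": 0.0, "T2": 1.0}
        a, b = make_samples(scores_a), make_samples(scores_b)
        d, lo, hi = oe.accuracy_difference(a, b, 0.5, 0.5, "LoR",
                                           n_boot=4000, seed=2)
        paired_width = hi - lo
        # naive unpaired bootstrap: resample the two cohorts independently
        lo_a, hi_a = oe.bootstrap_ci(a, 0.5, "LoR", n_boot=4000, seed=3)
        lo_b, hi_b = oe.bootstrap_ci(b, 0.5, "LoR", n_boot=4000, seed=4)
        unpaired_width = np.hypot(hi_a - lo_a, hi_b - lo_b)
        assert paired_width < unpaired_width
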