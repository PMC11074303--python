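import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from splitthz import evaluate
from splitthz.errors import UndefinedAUCError


def brute_force_auc(scores, positives):
    """Pair-counting oracle: concordant pairs (ties half) over all pos x neg pairs."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    total = 0.0
    for sp, sn in itertools.product(pos, neg):
        total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestTTest:
    def test_identical_samples(self):
        r = evaluate.two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert r.confidence_interval[0] < 0 < r.confidence_interval[1]

    def test_degrees_of_freedom_pooled_convention(self):
        """Two groups of 102 pixels give df = 202 under the pooled t-test."""
        rng = np.random.default_rng(0)
        r = evaluate.two_sample_ttest(rng.normal(1, 1, 102), rng.normal(0, 1, 102))
        assert r.degrees_of_freedom == 202

    def test_matches_hand_computation(self):
        """a=(1,2,3), b=(2,3,4): diff=-1, pooled sd=1, t=-sqrt(3/2)."""
        r = evaluate.two_sample_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        t_hand = -1.0 / (1.0 * math.sqrt(1 / 3 + 1 / 3))
        assert r.t_statistic == pytest.approx(t_hand, abs=1e-12)
        assert r.pooled_sd == pytest.approx(1.0, abs=1e-12)
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t_hand), 4), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0.5, 1.2, 40), rng.normal(0.0, 1.2, 55)
        r = evaluate.two_sample_ttest(a, b)
        sp = stats.ttest_ind(a, b, equal_var=True)
        assert r.t_statistic == pytest.approx(sp.statistic, rel=1e-12)
        assert r.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_ci_and_p_consistent_at_alpha_05(self):
        rng = np.random.default_rng(2)
        for shift in (0.0, 0.3, 2.0):
            a, b = rng.normal(shift, 1, 30), rng.normal(0, 1, 30)
            r = evaluate.two_sample_ttest(a, b)
            outside = not (r.confidence_interval[0] <= 0 <= r.confidence_interval[1])
            assert (r.p_value < 0.05) == outside

    def test_extreme_t_has_finite_log10p(self):
        r = evaluate.two_sample_ttest(np.arange(100) + 50.0, np.arange(100.0) * 0.01)
        assert np.isfinite(r.log10_p) and r.log10_p < -30

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        a = np.array([1.0, 2.0, 4.0, 4.5])
        b = np.array([2.0, 3.0, 5.0])
        r1 = evaluate.two_sample_ttest(a, b)
        r2 = evaluate.two_sample_ttest(c * a, c * b)
        assert r2.t_statistic == pytest.approx(r1.t_statistic, rel=1e-9)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-9)

    def test_zero_variance_unequal_means_is_degenerate(self):
        with pytest.raises(ZeroDivisionError):
            evaluate.two_sample_ttest([1.0, 1.0], [2.0, 2.0])


class TestAUC:
    def test_perfect_separation(self):
        assert evaluate.auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert evaluate.auc([5.0] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_matches_pair_counting_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            scores = rng.integers(0, 5, n).astype(float)  # integer scores force ties
            positives = np.zeros(n, bool)
            positives[rng.choice(n, n // 2, replace=False)] = True
            assert evaluate.auc(scores, positives) == pytest.approx(
                brute_force_auc(scores, positives), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal(50)
        positives = rng.random(50) > 0.5
        a1 = evaluate.auc(scores, positives)
        a2 = evaluate.auc(np.exp(3 * scores), positives)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_negation_complements(self):
        rng = np.random.default_rng(6)
        scores = rng.integers(0, 4, 30).astype(float)
        positives = rng.random(30) > 0.4
        assert evaluate.auc(scores, positives) + evaluate.auc(-scores, positives) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            evaluate.auc([1.0, 2.0], [1, 1])


class TestBestThreshold:
    def test_perfect_separation_reports_full_sensitivity(self):
        thr, sens, spec = evaluate.best_threshold([1, 2, 10, 11], [0, 0, 1, 1])
        assert sens == 1.0 and spec == 1.0
        assert 2 < thr <= 10

    def test_uninformative_scores_give_zero_j(self):
        thr, sens, spec = evaluate.best_threshold([3.0] * 6, [1, 0, 1, 0, 1, 0])
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 6, 15).astype(float)
        positives = rng.random(15) > 0.5
        if positives.all() or not positives.any():
            positives[0] = ~positives[0]
        thr, sens, spec = evaluate.best_threshold(scores, positives)
        best_j = -np.inf
        for t in np.concatenate([np.unique(scores), [np.inf]]):
            pred = scores >= t
            s = (pred & positives).sum() / positives.sum()
            q = (~pred & ~positives).sum() / (~positives).sum()
            best_j = max(best_j, s + q - 1)
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)

    def test_ties_break_toward_sensitivity(self):
        # J identical at two thresholds; the more sensitive one must win
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        positives = np.array([0, 1, 0, 1], bool)
        thr, sens, _ = evaluate.best_threshold(scores, positives)
        assert sens == 1.0


class TestClassificationReport:
    def test_printed_precision_recall_give_printed_f1(self):
        """Precision 0.97 and recall 0.93 combine to F1 = 0.95 at 2 d.p."""
        f1 = 2 * 0.97 * 0.93 / (0.97 + 0.93)
        assert round(f1, 2) == 0.95

    def test_perfect_predictions(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        rep = evaluate.classification_report(y, y)
        assert (rep.per_class[["accuracy", "precision", "recall", "f1"]] == 1.0).all().all()
        assert rep.overall_accuracy == 1.0

    def test_hand_confusion_matrix(self):
        """mu=8, mu1=85, Gamma=3, Gamma1=4 (N=100): accuracy .93, P=8/11, R=8/12."""
        y_true = np.array([1] * 12 + [0] * 88)
        y_pred = np.concatenate([np.ones(8), np.zeros(4), np.ones(3), np.zeros(85)]).astype(int)
        rep = evaluate.classification_report(y_true, y_pred)
        row = rep.per_class.loc[1]
        k = rep.confusion.counts[1]
        assert (k["mu"], k["mu1"], k["gamma"], k["gamma1"]) == (8, 85, 3, 4)
        assert row["accuracy"] == pytest.approx(0.93)
        assert row["precision"] == pytest.approx(8 / 11)
        assert row["recall"] == pytest.approx(8 / 12)
        p, r = 8 / 11, 8 / 12
        assert row["f1"] == pytest.approx(2 * p * r / (p + r))

    def test_micro_average_matches_overall_accuracy(self):
        rng = np.random.default_rng(8)
        y_true = rng.integers(1, 4, 60)
        y_pred = rng.integers(1, 4, 60)
        rep = evaluate.classification_report(y_true, y_pred)
        total_tp = sum(rep.confusion.counts[c]["mu"] for c in rep.confusion.classes)
        assert total_tp / 60 == pytest.approx(rep.overall_accuracy)

    def test_undefined_metric_is_nan_with_warning(self):
        y_true = np.array([1, 1, 2, 2])
        y_pred = np.array([1, 1, 1, 1])  # class 2 never predicted -> precision undefined
        with pytest.warns(UserWarning, match="undefined"):
            rep = evaluate.classification_report(y_true, y_pred)
        assert math.isnan(rep.per_class.loc[2, "precision"])

    def test_length_mismatch(self):
        with pytest.raises(Exception):
            evaluate.classification_report([1, 2], [1])


class TestLearningCurves:
    def _log(self, vals, key="val_acc"):
        return [{"round": i + 1, "loss": 1.0, key: v} for i, v in enumerate(vals)]

    def test_monotone_log_argmax_is_last(self):
        lc = evaluate.learning_curves(self._log(np.linspace(0.5, 0.9, 12)))
        assert lc.best_val_epoch == 12

    def test_planted_max_found(self):
        vals = [0.5, 0.6, 0.62, 0.64, 0.66, 0.68, 0.9, 0.7, 0.71, 0.69]
        lc = evaluate.learning_curves(self._log(vals))
        assert lc.best_val_epoch == 7

    def test_plateau_flag_on_constant_tail(self):
        vals = list(np.linspace(0.5, 0.8, 10)) + [0.8] * 12
        lc = evaluate.learning_curves(self._log(vals))
        assert lc.plateau

    def test_no_plateau_while_improving(self):
        lc = evaluate.learning_curves(self._log(np.linspace(0.1, 0.9, 25)))
        assert not lc.plateau
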