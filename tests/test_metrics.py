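"""Metric correctness: confusion counts, averaging identities, rank AUC, CV CIs."""

import numpy as np
import pytest
from scipy import stats

from portnet.metrics import (MetricsReport, confusion, cv_report, roc_auc,
                             scalar_metrics)


def brute_force_confusion(labels, preds, k):
    m = np.zeros((k, k), dtype=int)
    for l, p in zip(labels, preds):
        m[l, p] += 1
    return m


def brute_force_auc(scores, positive):
    pos, neg = scores[positive], scores[~positive]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        cc = confusion([0, 1, 2], [0, 1, 2])
        assert np.array_equal(cc.matrix, np.eye(3, dtype=int))
        assert cc.tp.tolist() == [1, 1, 1]
        assert cc.fp.sum() == cc.fn.sum() == 0

    def test_systematic_misclassification(self):
        cc = confusion([0, 0], [1, 1])
        assert cc.tp[0] == 0 and cc.fn[0] == 2 and cc.fp[1] == 2

    def test_counts_partition_n(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 100)
        preds = rng.integers(0, 4, 100)
        cc = confusion(labels, preds)
        np.testing.assert_array_equal(cc.tp + cc.fp + cc.fn + cc.tn, 100)

    def test_agrees_with_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, 100)
        preds = rng.integers(0, 3, 100)
        cc = confusion(labels, preds, num_classes=3)
        np.testing.assert_array_equal(cc.matrix,
                                      brute_force_confusion(labels, preds, 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestScalarMetrics:
    def test_binary_hand_example(self):
        # TP=50 TN=40 FP=5 FN=5 -> ACC = 90/100
        labels = [1] * 55 + [0] * 45
        preds = [1] * 50 + [0] * 5 + [0] * 40 + [1] * 5
        cc = confusion(labels, preds)
        assert scalar_metrics(cc, "micro").acc == pytest.approx(0.90)

    def test_micro_identity_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            k = int(rng.integers(2, 6))
            cc = confusion(rng.integers(0, k, n), rng.integers(0, k, n),
                           num_classes=k)
            r = scalar_metrics(cc, "micro")
            assert r.pre == r.rec == r.acc

    def test_f1_equals_p_when_pre_equals_rec(self):
        # symmetric confusion: every class has PRE == REC
        cc = confusion([0, 0, 1, 1, 2, 2], [0, 1, 1, 2, 2, 0])
        for mode in ("micro", "macro"):
            r = scalar_metrics(cc, mode)
            assert r.f1 == pytest.approx(r.pre) == pytest.approx(r.rec)

    def test_macro_differs_from_micro_on_imbalance(self):
        cc = confusion([0] * 90 + [1] * 10, [0] * 90 + [0] * 5 + [1] * 5)
        micro = scalar_metrics(cc, "micro")
        macro = scalar_metrics(cc, "macro")
        assert micro.acc == pytest.approx(0.95)
        assert macro.rec < micro.rec  # minority-class recall drags the mean

    def test_acc_invariant_under_class_relabeling(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 3, 60)
        preds = rng.integers(0, 3, 60)
        base = scalar_metrics(confusion(labels, preds, 3), "macro")
        perm = np.array([2, 0, 1])
        permuted = scalar_metrics(confusion(perm[labels], perm[preds], 3), "macro")
        assert permuted.acc == pytest.approx(base.acc)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scalar_metrics(confusion([], []), "micro")


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        _, macro = roc_auc(scores, [0, 0, 1, 1])
        assert macro == 1.0

    def test_all_tied_scores_give_half(self):
        scores = np.full((10, 2), 0.5)
        _, macro = roc_auc(scores, [0, 1] * 5)
        assert macro == 0.5

    def test_rank_formulation_matches_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(8, 40))
            k = int(rng.integers(2, 5))
            scores = np.round(rng.random((n, k)), 2)  # rounding induces ties
            labels = rng.integers(0, k, n)
            labels[:k] = np.arange(k)  # every class present
            curves, macro = roc_auc(scores, labels)
            for c in curves:
                expected = brute_force_auc(scores[:, c.class_id],
                                           labels == c.class_id)
                assert c.auc == pytest.approx(expected, abs=1e-12)

    def test_rank_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(6)
        scores = rng.random((50, 3))
        labels = rng.integers(0, 3, 50)
        curves, macro = roc_auc(scores, labels)
        for c in curves:
            expected = roc_auc_score((labels == c.class_id).astype(int),
                                     scores[:, c.class_id])
            assert c.auc == pytest.approx(expected, abs=1e-12)

    def test_roc_curves_monotone(self):
        rng = np.random.default_rng(7)
        curves, _ = roc_auc(rng.random((30, 3)), rng.integers(0, 3, 30))
        for c in curves:
            assert np.all(np.diff(c.fpr) >= 0)
            assert np.all(np.diff(c.tpr) >= 0)
            assert c.fpr[0] == 0 and c.tpr[0] == 0
            assert c.fpr[-1] == 1 and c.tpr[-1] == 1

    def test_absent_class_excluded_with_warning(self):
        scores = np.random.default_rng(8).random((10, 3))
        labels = np.array([0, 1] * 5)  # class 2 absent
        with pytest.warns(UserWarning, match="class 2"):
            curves, macro = roc_auc(scores, labels)
        assert {c.class_id for c in curves} == {0, 1}


class TestCvReport:
    def _reports(self, accs):
        return [MetricsReport(acc=a, pre=a, rec=a, f1=a, averaging="macro", n=10)
                for a in accs]

    def test_identical_folds_zero_halfwidth(self):
        summary = cv_report(self._reports([0.9] * 5))
        mean, half = summary.stats["acc"]
        assert mean == pytest.approx(0.9) and half == 0.0

    def test_t_interval_hand_example(self):
        vals = [1.0, 0.9, 1.0, 0.9, 1.0]
        summary = cv_report(self._reports(vals))
        mean, half = summary.stats["acc"]
        sd = np.std(vals, ddof=1)
        assert mean == pytest.approx(0.96)
        assert half == pytest.approx(stats.t.ppf(0.975, 4) * sd / np.sqrt(5))
        assert stats.t.ppf(0.975, 4) == pytest.approx(2.776, abs=5e-4)

    def test_fold_order_invariance(self):
        a = cv_report(self._reports([0.8, 0.9, 1.0]))
        b = cv_report(self._reports([1.0, 0.8, 0.9]))
        assert a.stats == b.stats

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            cv_report(self._reports([0.9]))
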