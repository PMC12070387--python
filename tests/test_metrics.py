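import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from twintower.errors import EmptyEvalError, RocError, ShapeMismatchError
from twintower.metrics import (
    ConfusionCounts,
    compute_metrics,
    confusion_counts,
    evaluate_predictions,
    f1_score,
    mean_report,
    roc_auc,
)


class TestConfusionCounts:
    def test_hand_enumeration(self):
        c = confusion_counts([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_perfect_prediction_has_no_errors(self):
        y = np.array([1, 0, 1, 1, 0])
        c = confusion_counts(y, y)
        assert c.fp == 0 and c.fn == 0 and c.total == 5

    def test_matches_exhaustive_loop_oracle(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, size=500)
        p = rng.integers(0, 2, size=500)
        tp = tn = fp = fn = 0
        for yi, pi in zip(y, p):
            if yi == 1 and pi == 1:
                tp += 1
            elif yi == 0 and pi == 0:
                tn += 1
            elif yi == 0 and pi == 1:
                fp += 1
            else:
                fn += 1
        c = confusion_counts(y, p)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_length_mismatch_raises(self):
        with pytest.raises(ShapeMismatchError):
            confusion_counts([1, 0], [1])

    def test_empty_raises(self):
        with pytest.raises(EmptyEvalError):
            confusion_counts([], [])


class TestDerivedMetrics:
    def test_accuracy_equals_agreement_rate(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=200)
        p = rng.integers(0, 2, size=200)
        report = compute_metrics(confusion_counts(y, p))
        assert report.accuracy == pytest.approx(np.mean(y == p))

    def test_f1_is_harmonic_mean_of_printed_pair(self):
        # precision 93.3% and recall 87.5% combine to an F1 of 90.3%
        assert round(f1_score(0.933, 0.875), 3) == 0.903

    @given(x=st.floats(min_value=0.01, max_value=1.0))
    def test_equal_precision_recall_is_f1_fixed_point(self, x):
        assert f1_score(x, x) == pytest.approx(x)

    def test_degenerate_zero_tp_flagged(self):
        report = compute_metrics(ConfusionCounts(tp=0, tn=3, fp=2, fn=4))
        assert report.precision == report.recall == report.f1 == 0.0
        assert report.degenerate

    def test_f1_bounded_by_precision_and_recall(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = ConfusionCounts(*rng.integers(1, 50, size=4))
            r = compute_metrics(c)
            assert min(r.precision, r.recall) - 1e-12 <= r.f1 <= max(r.precision, r.recall) + 1e-12
            for v in (r.accuracy, r.precision, r.recall, r.f1):
                assert 0.0 <= v <= 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=100)
        p = rng.integers(0, 2, size=100)
        perm = rng.permutation(100)
        a = compute_metrics(confusion_counts(y, p))
        b = compute_metrics(confusion_counts(y[perm], p[perm]))
        assert a.to_dict() == b.to_dict()


def _mann_whitney_auc(y, s):
    """All-pairs concordance: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert curve.auc == pytest.approx(1.0)
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=60)
        s = rng.random(60)
        assert roc_auc(y, 1 - s).auc == pytest.approx(1 - roc_auc(y, s).auc)

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_matches_pair_counting_oracle(self, with_ties):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=200)
        y[:2] = [0, 1]  # guarantee both classes
        s = rng.random(200)
        if with_ties:
            s = np.round(s, 1)
        assert roc_auc(y, s).auc == pytest.approx(_mann_whitney_auc(y, s), abs=1e-9)
        assert roc_auc(y, s).auc == pytest.approx(roc_auc_score(y, s), abs=1e-9)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        pts = np.array(roc_auc(y, np.round(rng.random(80), 1)).points)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_raises(self):
        with pytest.raises(RocError):
            roc_auc([1, 1, 1], [0.2, 0.5, 0.9])


class TestReports:
    def test_evaluate_predictions_thresholds_at_half(self):
        y = np.array([1, 0, 1, 0])
        s = np.array([0.5, 0.49, 0.9, 0.2])
        r = evaluate_predictions(y, s)
        assert r.counts.tp == 2 and r.counts.tn == 2
        assert r.auc == pytest.approx(1.0)

    def test_mean_report_averages_folds(self):
        r1 = compute_metrics(ConfusionCounts(4, 4, 1, 1))
        r2 = compute_metrics(ConfusionCounts(3, 3, 2, 2))
        m = mean_report([r1, r2])
        assert m.accuracy == pytest.approx((r1.accuracy + r2.accuracy) / 2)
        assert m.counts.tp == 7
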