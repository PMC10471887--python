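"""Metric definitions: confusion tallies, macro F1, SN/SP, AUC, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcfcnn.evaluation import (
    PredictionSet,
    aggregate,
    aggregate_pooled,
    compute_metrics,
    confusion,
    mann_whitney_auc,
)
from dcfcnn.exceptions import DataError


def _pset(y, yhat, s=None):
    y = np.asarray(y)
    s = np.asarray(s if s is not None else yhat, dtype=float)
    return PredictionSet([str(i) for i in range(len(y))], y, np.asarray(yhat), s)


def test_confusion_all_correct():
    assert confusion([1, 1, 1, 0, 0], [1, 1, 1, 0, 0]) == (3, 0, 2, 0)


def test_confusion_hand_tally():
    # 8 samples: TP=3, FN=1, TN=2, FP=2 -- verified by per-sample enumeration
    y_true = [1, 1, 1, 1, 0, 0, 0, 0]
    y_pred = [1, 1, 1, 0, 0, 0, 1, 1]
    tp = sum(t == p == 1 for t, p in zip(y_true, y_pred))
    fp = sum(t == 0 and p == 1 for t, p in zip(y_true, y_pred))
    tn = sum(t == p == 0 for t, p in zip(y_true, y_pred))
    fn = sum(t == 1 and p == 0 for t, p in zip(y_true, y_pred))
    assert confusion(y_true, y_pred) == (tp, fp, tn, fn) == (3, 2, 2, 1)


def test_confusion_single_class_set():
    assert confusion([1, 1], [1, 0]) == (1, 0, 0, 1)  # TN = FP = 0


def test_perfect_predictions_score_one():
    m = compute_metrics(_pset([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]))
    assert m["acc"] == m["f1_macro"] == m["sn"] == m["sp"] == 1.0
    assert m["auc"] == 1.0


def test_auc_three_quarters_by_pair_enumeration():
    # malignant scores {0.9, 0.8}, benign {0.85, 0.1}: 3 of 4 pairs concordant
    m = compute_metrics(_pset([1, 1, 0, 0], [1, 1, 1, 0], [0.9, 0.8, 0.85, 0.1]))
    assert m["auc"] == pytest.approx(0.75)


def test_hand_worked_metric_entry():
    y_true = [1, 1, 1, 1, 0, 0, 0, 0]
    y_pred = [1, 1, 1, 0, 0, 0, 1, 1]
    m = compute_metrics(_pset(y_true, y_pred))
    assert m["sn"] == pytest.approx(0.75)
    assert m["sp"] == pytest.approx(0.5)
    assert m["acc"] == pytest.approx(0.625)
    # per-class F1 by hand: malignant prec 3/5, rec 3/4 -> 2/3;
    # benign prec 2/3, rec 1/2 -> 4/7; macro = (2/3 + 4/7)/2
    assert m["f1_macro"] == pytest.approx((2 / 3 + 4 / 7) / 2)


def test_single_class_fold_reports_undefined_auc():
    with pytest.warns(UserWarning):
        m = compute_metrics(_pset([1, 1, 1], [1, 1, 0], [0.9, 0.8, 0.3]))
    assert m["auc"] is None
    assert m["sp"] is None  # zero benign denominator


def test_label_swap_symmetry():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 30)
    yhat = rng.integers(0, 2, 30)
    m = compute_metrics(_pset(y, yhat))
    m_swap = compute_metrics(_pset(1 - y, 1 - yhat))
    assert m_swap["sn"] == pytest.approx(m["sp"])
    assert m_swap["sp"] == pytest.approx(m["sn"])
    assert m_swap["acc"] == pytest.approx(m["acc"])


@given(st.integers(0, 10_000))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_trapezoidal_auc_equals_mann_whitney_oracle(seed):
    """Two routes, one number, to 1e-12 -- including tied scores."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    y = rng.integers(0, 2, n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    scores = np.round(rng.random(n), int(rng.integers(1, 4)))  # force ties often
    m = compute_metrics(_pset(y, (scores > 0.5).astype(int), scores))
    assert m["auc"] == pytest.approx(mann_whitney_auc(y, scores), abs=1e-12)


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, 20)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    s = rng.random(20)
    a1 = compute_metrics(_pset(y, (s > 0.5).astype(int), s))["auc"]
    s2 = 1.0 / (1.0 + np.exp(-(4 * s - 2)))  # strictly increasing into [0,1]
    a2 = compute_metrics(_pset(y, (s > 0.5).astype(int), s2))["auc"]
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_aggregate_of_identical_folds_equals_any_fold():
    fold = compute_metrics(_pset([1, 0], [1, 0], [0.9, 0.1]))
    agg = aggregate([fold, fold, fold])
    for k in ("acc", "f1_macro", "sn", "sp", "auc"):
        assert agg["mean"][k] == pytest.approx(fold[k])


def test_aggregate_mean_arithmetic():
    f1 = compute_metrics(_pset([1, 0], [1, 0], [0.9, 0.1]))  # acc 1.0
    f2 = compute_metrics(_pset([1, 0, 1, 0, 1, 1, 1, 1, 1, 1],
                               [1, 0, 0, 0, 1, 1, 1, 1, 1, 1]))  # acc 0.9
    agg = aggregate([f1, f2])
    assert agg["mean"]["acc"] == pytest.approx(0.95)


def test_pooled_differs_from_mean_on_imbalanced_folds():
    # fold A: 2 samples all correct; fold B: 10 samples, 5 correct
    fa = _pset([1, 0], [1, 0], [0.9, 0.1])
    fb = _pset([1] * 5 + [0] * 5, [1, 1, 1, 1, 1, 1, 1, 1, 1, 1])
    mean_acc = aggregate([compute_metrics(fa), compute_metrics(fb)])["mean"]["acc"]
    pooled_acc = aggregate_pooled([fa, fb])["acc"]
    assert mean_acc == pytest.approx((1.0 + 0.5) / 2)
    assert pooled_acc == pytest.approx(7 / 12)
    assert mean_acc != pooled_acc


def test_undefined_fold_metrics_excluded_with_count():
    with pytest.warns(UserWarning):
        bad = compute_metrics(_pset([1, 1], [1, 1], [0.9, 0.8]))
    good = compute_metrics(_pset([1, 0], [1, 0], [0.9, 0.1]))
    agg = aggregate([good, bad])
    assert agg["mean"]["auc"] == pytest.approx(1.0)
    assert agg["mean"]["excluded_folds"]["auc"] == 1


def test_scores_outside_unit_interval_rejected():
    with pytest.raises(DataError):
        _pset([1, 0], [1, 0], [1.5, 0.0])


def test_empty_prediction_set_rejected():
    with pytest.raises(DataError):
        confusion([], [])
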