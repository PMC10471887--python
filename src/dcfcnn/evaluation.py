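"""Metric suite: accuracy, macro F1, sensitivity, specificity, AUC.

The malignant class is positive: sensitivity is malignant recall
TP/(TP+FN), specificity is benign recall TN/(TN+FP). AUC is the area under
the ROC of the malignant score (trapezoidal rule, equal to the Mann-Whitney
statistic with ties counted one half). Folds missing a class yield
undefined (None) AUC/SN/SP rather than a misleading zero.

Aggregation over folds is reported both as the unweighted mean of per-fold
metrics (the headline) and as pooled metrics over the concatenated test
predictions; the published tables do not state which rule they used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

from .exceptions import DataError

__all__ = ["PredictionSet", "confusion", "compute_metrics", "aggregate"]

METRIC_KEYS = ("acc", "f1_macro", "sn", "sp", "auc")


@dataclass
class PredictionSet:
    """Per-sample predictions for one test fold (1 = malignant)."""

    scene_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true)
        self.y_pred = np.asarray(self.y_pred)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.y_true)
        if not (len(self.y_pred) == len(self.scores) == len(self.scene_ids) == n):
            raise DataError("prediction set fields must have equal length")
        if n and (self.scores.min() < 0 or self.scores.max() > 1):
            raise DataError("malignant scores must lie in [0, 1]")


def confusion(y_true, y_pred):
    """(TP, FP, TN, FN) with malignant (1) as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise DataError("cannot tally an empty prediction set")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


def compute_metrics(preds: PredictionSet) -> dict:
    """One fold's metric entry; single-class folds get undefined AUC."""
    y, yhat, s = preds.y_true, preds.y_pred, preds.scores
    tp, fp, tn, fn = confusion(y, yhat)
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    sn = tp / (tp + fn) if (tp + fn) else None
    sp = tn / (tn + fp) if (tn + fp) else None
    f1m = float(f1_score(y, yhat, labels=[0, 1], average="macro", zero_division=0))
    if len(np.unique(y)) < 2:
        warnings.warn("single-class fold: AUC undefined", stacklevel=2)
        auc = None
    else:
        auc = float(roc_auc_score(y, s))
    return {"acc": acc, "f1_macro": f1m, "sn": sn, "sp": sp, "auc": auc,
            "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
            "n": int(n)}


def mann_whitney_auc(y_true, scores) -> float:
    """Pairwise AUC oracle: P(score_mal > score_ben) + 0.5 P(tie)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("AUC requires both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def aggregate(fold_reports: list[dict]) -> dict:
    """Mean-of-folds and pooled aggregation of per-fold metric entries."""
    if not fold_reports:
        raise DataError("need at least one fold report")
    mean_entry, excluded = {}, {}
    for key in METRIC_KEYS:
        vals = [r[key] for r in fold_reports if r.get(key) is not None]
        mean_entry[key] = float(np.mean(vals)) if vals else None
        excluded[key] = len(fold_reports) - len(vals)
    cm = {k: sum(r["confusion"][k] for r in fold_reports)
          for k in ("tp", "fp", "tn", "fn")}
    mean_entry["excluded_folds"] = excluded
    return {"mean": mean_entry, "pooled_confusion": cm,
            "n_folds": len(fold_reports)}


def aggregate_pooled(prediction_sets: list[PredictionSet]) -> dict:
    """Pooled metrics: concatenate all test predictions, compute once."""
    if not prediction_sets:
        raise DataError("need at least one prediction set")
    pooled = PredictionSet(
        scene_ids=[i for p in prediction_sets for i in p.scene_ids],
        y_true=np.concatenate([p.y_true for p in prediction_sets]),
        y_pred=np.concatenate([p.y_pred for p in prediction_sets]),
        scores=np.concatenate([p.scores for p in prediction_sets]),
    )
    return compute_metrics(pooled)


def format_report(per_fold: list[dict], agg: dict) -> dict:
    """JSON-ready report with percentages to 2 decimals, AUC to 3."""

    def fmt(entry):
        out = {}
        for k in ("acc", "f1_macro", "sn", "sp"):
            out[k] = None if entry[k] is None else round(100.0 * entry[k], 2)
        out["auc"] = None if entry["auc"] is None else round(entry["auc"], 3)
        return out

    return {
        "schema_version": 1,
        "per_fold": [dict(fmt(r), confusion=r["confusion"], n=r["n"])
                     for r in per_fold],
        "mean_of_folds": fmt(agg["mean"]),
        "pooled_confusion": agg["pooled_confusion"],
    }
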