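"""Training protocol: stratified five-fold CV, SGD, best-train-accuracy selection.

The published protocol trains with plain SGD (learning rate 0.001, momentum
0.9, weight decay 1e-6, batch size 16, 200 epochs), splits scenes into five
stratified folds and selects, per fold, the epoch whose overall training-set
classification accuracy is highest (earliest epoch on ties). That selection
accuracy is computed here by a full-training-set forward pass using batch
statistics with running statistics frozen, making the recorded history a
pure function of the weights.

A patient-grouped splitting mode is provided for leakage-safe evaluation;
the default stratifies at scene level, which is the only way the published
per-fold benign counts can arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import nn
from .architecture import ArchitectureConfig, DCFCNN, build_dcfcnn
from .exceptions import ConfigError, DataError, NumericalError

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "TrainResult",
    "make_folds",
    "train_fold",
    "cross_validate",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-6
    batch_size: int = 16
    epochs: int = 200
    n_folds: int = 5
    seed: int = 0
    grouping: str = "scene"

    def __post_init__(self):
        if min(self.learning_rate, self.momentum, self.weight_decay) < 0:
            raise ConfigError("rates must be >= 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.grouping not in ("scene", "patient"):
            raise ConfigError("grouping must be 'scene' or 'patient'")


@dataclass
class FoldSplit:
    """Per fold: (train indices, test indices) into the manifest order."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    scene_ids: list[str]

    def __len__(self):
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)

    def id_folds(self):
        return [([self.scene_ids[i] for i in tr], [self.scene_ids[i] for i in te])
                for tr, te in self.folds]


@dataclass
class TrainResult:
    """One fold's training record."""

    loss_history: list[float]
    acc_history: list[float]
    best_epoch: int  # 1-based
    best_state: dict = field(repr=False, default_factory=dict)


def make_folds(labels, cfg: TrainConfig, scene_ids=None, groups=None) -> FoldSplit:
    """Deterministic stratified k-fold split of scenes.

    ``labels`` may be a manifest (with ``.labels`` / ``.patient_ids``) or an
    array of labels. With ``grouping='patient'`` all scenes of a patient
    share a fold.
    """
    if hasattr(labels, "labels"):  # DatasetManifest
        manifest = labels
        y = manifest.labels
        scene_ids = [s.scene_id for s in manifest.samples]
        groups = manifest.patient_ids if cfg.grouping == "patient" else None
    else:
        y = np.asarray(labels)
        if scene_ids is None:
            scene_ids = [str(i) for i in range(len(y))]
    if len(y) == 0:
        raise DataError("cannot split an empty manifest")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cfg.n_folds and cfg.grouping == "scene":
        raise DataError(
            f"smallest class has {counts.min()} members, fewer than "
            f"n_folds={cfg.n_folds}")
    if cfg.grouping == "patient":
        if groups is None:
            raise DataError("patient grouping requires patient ids")
        splitter = StratifiedGroupKFold(n_splits=cfg.n_folds, shuffle=True,
                                        random_state=cfg.seed)
        split = splitter.split(np.zeros(len(y)), y, groups=groups)
    else:
        splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                                   random_state=cfg.seed)
        split = splitter.split(np.zeros(len(y)), y)
    folds = [(np.asarray(tr), np.asarray(te)) for tr, te in split]
    return FoldSplit(folds=folds, scene_ids=list(scene_ids))


def _train_set_accuracy(model: DCFCNN, x: np.ndarray, y: np.ndarray,
                        max_chunk: int = 512) -> float:
    """Overall training-set accuracy under batch statistics, stats frozen."""
    correct = 0
    for lo in range(0, len(x), max_chunk):
        logits = model.forward(x[lo:lo + max_chunk], training=True,
                               update_stats=False)
        correct += int((logits.argmax(axis=1) == y[lo:lo + max_chunk]).sum())
    return correct / len(x)


def train_fold(model: DCFCNN, x: np.ndarray, y: np.ndarray,
               cfg: TrainConfig, fold_index: int = 0) -> TrainResult:
    """Train one fold and return the best-training-accuracy checkpoint.

    ``x`` is a preprocessed (N, 3, H, W) float array, ``y`` integer labels.
    Shuffling is reseeded per epoch from (seed, fold, epoch); the incomplete
    final batch is kept.
    """
    if len(x) == 0:
        raise DataError("training fold is empty")
    x = np.ascontiguousarray(x, dtype=model.dtype)
    y = np.asarray(y)
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate,
                 momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    loss_hist, acc_hist = [], []
    best_acc, best_epoch, best_state = -1.0, -1, None
    for epoch in range(1, cfg.epochs + 1):
        order = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, fold_index, epoch])
        ).permutation(len(x))
        losses = []
        for lo in range(0, len(x), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = model.forward(x[idx], training=True)
            loss, dlogits = nn.cross_entropy_with_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise NumericalError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}")
            opt.zero_grad()
            model.backward(dlogits.astype(model.dtype))
            opt.step()
            losses.append(loss)
        acc = _train_set_accuracy(model, x, y)
        loss_hist.append(float(np.mean(losses)))
        acc_hist.append(acc)
        if acc > best_acc:  # strict: ties keep the earliest epoch
            best_acc, best_epoch = acc, epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    return TrainResult(loss_history=loss_hist, acc_history=acc_hist,
                       best_epoch=best_epoch, best_state=best_state)


def predict_scores(model: DCFCNN, x: np.ndarray, batch: int = 64) -> np.ndarray:
    """Malignant softmax probabilities in evaluation mode."""
    out = []
    for lo in range(0, len(x), batch):
        logits = model.forward(np.ascontiguousarray(x[lo:lo + batch], dtype=model.dtype),
                               training=False)
        out.append(nn.softmax(logits)[:, 1])
    return np.concatenate(out) if out else np.zeros(0)


def cross_validate(x: np.ndarray, y: np.ndarray, arch: ArchitectureConfig,
                   cfg: TrainConfig, scene_ids=None, groups=None):
    """Full protocol: stratified folds, per-fold training and test predictions.

    Returns ``(fold_predictions, fold_results, split)`` where
    ``fold_predictions`` is a list of dicts with test indices, true labels,
    predicted labels and malignant scores.
    """
    split = make_folds(y, cfg, scene_ids=scene_ids, groups=groups)
    preds, results = [], []
    for k, (tr, te) in enumerate(split):
        model = build_dcfcnn(arch, seed=None)
        model.initialize(np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 1000 + k])))
        res = train_fold(model, x[tr], y[tr], cfg, fold_index=k)
        model.load_state_dict(res.best_state)
        scores = predict_scores(model, x[te])
        preds.append({
            "test_index": te,
            "scene_ids": [split.scene_ids[i] for i in te],
            "y_true": y[te],
            "y_pred": (scores >= 0.5).astype(np.int64),
            "scores": scores,
        })
        results.append(res)
    return preds, results, split
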