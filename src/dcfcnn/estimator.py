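"""scikit-learn style estimators wrapping the network and preprocessing.

``PatchPreprocessor`` is a transformer (resize -> center crop -> per-channel
standardisation with statistics fitted on the training split) and
``DCFCNNClassifier`` a classifier with the published training protocol.
Both follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with trailing underscores) so they compose with pipelines and
model-selection utilities; inputs are image stacks of shape (N, H, W, 3).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .architecture import ArchitectureConfig, build_dcfcnn
from .exceptions import DataError
from .preprocessing import (PreprocessConfig, center_crop, channel_stats,
                            normalize_standardize, resize_short_edge)
from .training import TrainConfig, train_fold

__all__ = ["PatchPreprocessor", "DCFCNNClassifier"]


def _check_images(X, dtype=None):
    X = np.asarray(X)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise DataError(f"expected (N, H, W, 3) image stack, got shape {X.shape}")
    return X if dtype is None else X.astype(dtype)


class PatchPreprocessor(TransformerMixin, BaseEstimator):
    """Resize/crop/standardise a stack of RGB scenes.

    ``fit`` computes per-channel mean/std on the (already resized and
    cropped) training images when no constants are supplied; ``transform``
    returns float32 arrays of shape (N, crop_size, crop_size, 3).
    """

    def __init__(self, short_edge=512, crop_size=448, channel_mean=None,
                 channel_std=None):
        self.short_edge = short_edge
        self.crop_size = crop_size
        self.channel_mean = channel_mean
        self.channel_std = channel_std

    def _spatial(self, X):
        return np.stack([
            center_crop(resize_short_edge(img, self.short_edge), self.crop_size)
            for img in X
        ])

    def fit(self, X, y=None):
        X = _check_images(X)
        # validates short_edge/crop_size relation as well
        PreprocessConfig(short_edge=self.short_edge, crop_size=self.crop_size,
                         channel_mean=self.channel_mean, channel_std=self.channel_std)
        cropped = self._spatial(X)
        if self.channel_mean is None or self.channel_std is None:
            mean, std = channel_stats(cropped)
        if self.channel_mean is not None:
            mean = tuple(self.channel_mean)
        if self.channel_std is not None:
            std = tuple(self.channel_std)
        self.channel_mean_, self.channel_std_ = mean, std
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def transform(self, X):
        check_is_fitted(self, "channel_mean_")
        X = _check_images(X)
        cfg = PreprocessConfig(short_edge=self.short_edge, crop_size=self.crop_size,
                               channel_mean=self.channel_mean_,
                               channel_std=self.channel_std_)
        return np.stack([normalize_standardize(img, cfg)
                         for img in self._spatial(X)])


class DCFCNNClassifier(ClassifierMixin, BaseEstimator):
    """Dual-branch CNN classifier with the published SGD protocol.

    Accepts fixed-size (N, H, W, 3) crops (uint8 or float). Channel
    standardisation statistics are fitted on the training images, so using
    the classifier inside a cross-validation loop automatically recomputes
    them per fold. Architecture switches mirror the ablation grid: disable
    ``use_channel_branch`` for the spatial-only variant, ``use_msf`` (with
    ``rs1_first_stride=1``) for the 1x1-stem variants, ``feature_reuse`` to
    unwire the multilevel fusion.
    """

    def __init__(self, n_mlf=3, feature_reuse=True, use_msf=True,
                 use_channel_branch=True, rs1_first_stride=2,
                 learning_rate=0.001, momentum=0.9, weight_decay=1e-6,
                 batch_size=16, epochs=200, random_state=0):
        self.n_mlf = n_mlf
        self.feature_reuse = feature_reuse
        self.use_msf = use_msf
        self.use_channel_branch = use_channel_branch
        self.rs1_first_stride = rs1_first_stride
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def _arch_config(self):
        return ArchitectureConfig(
            n_mlf=self.n_mlf, feature_reuse=self.feature_reuse,
            use_msf=self.use_msf, use_channel_branch=self.use_channel_branch,
            rs1_first_stride=self.rs1_first_stride)

    def _train_config(self):
        return TrainConfig(learning_rate=self.learning_rate, momentum=self.momentum,
                           weight_decay=self.weight_decay, batch_size=self.batch_size,
                           epochs=self.epochs, seed=self.random_state)

    def _standardize(self, X):
        x = _check_images(X, dtype=np.float32) / 255.0
        x = (x - np.asarray(self.channel_mean_, np.float32)) \
            / np.asarray(self.channel_std_, np.float32)
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def fit(self, X, y):
        X = _check_images(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise DataError("X and y length mismatch")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise DataError(
                f"binary classifier: expected 2 classes, got {len(self.classes_)}")
        mean, std = channel_stats(X)
        self.channel_mean_, self.channel_std_ = mean, std
        x = self._standardize(X)
        cfg = self._train_config()
        model = build_dcfcnn(self._arch_config())
        model.initialize(np.random.default_rng(
            np.random.SeedSequence([int(self.random_state) & 0x7FFFFFFF, 7])))
        result = train_fold(model, x, y_enc, cfg)
        model.load_state_dict(result.best_state)
        self.model_ = model
        self.history_ = {"loss": result.loss_history, "acc": result.acc_history}
        self.best_epoch_ = result.best_epoch
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        x = self._standardize(X)
        out = []
        for lo in range(0, len(x), 64):
            logits = self.model_.forward(x[lo:lo + 64], training=False)
            out.append(nn.softmax(logits))
        return np.concatenate(out)

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
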