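"""Scikit-learn style estimator wrapping the segmentation network.

``DenseNetSegmenter`` follows the sklearn estimator contract: all
constructor arguments are hyperparameters stored verbatim, ``fit`` learns
from arrays, fitted state lives in trailing-underscore attributes, and
``get_params``/``set_params`` come from :class:`sklearn.base.BaseEstimator`
so the model composes with pipelines and model selection.

X is a stack of grayscale images shaped (n, h, w) with values in [0, 1];
y is the matching stack of binary lesion masks.  ``predict`` returns
masks, ``predict_proba`` per-pixel class probabilities, ``score`` the mean
lesion Dice (DSC1), and ``diagnose`` image-level calls from the
pixel-count rule.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .arch import SegmentationNetwork, count_parameters
from .config import NetworkConfig, TrainingConfig
from .metrics import dice
from .pipeline import diagnose, predict_masks, train


class DenseNetSegmenter(BaseEstimator):
    """Multi-scale scSE fully convolutional DenseNet for lesion segmentation.

    Parameters mirror :class:`NetworkConfig` and :class:`TrainingConfig`;
    see those classes for semantics.  ``validation_fraction`` is used when
    ``fit`` is not given an explicit validation set.
    """

    def __init__(self, growth_rate=12, layers_per_block=(4, 5, 7, 10, 12, 15),
                 initial_channels=48, in_channels=3, multiscale=True,
                 ms_kernels=(3, 5, 7), ms_filters_per_branch=None, scse=True,
                 scse_reduction=2, scse_placement="per_block", dropout=0.2,
                 num_classes=2, loss="swcel", boundary_iterations=2,
                 learning_rate=1e-4, weight_decay=1e-4, batch_size=4,
                 max_epochs=200, patience=20, flip_prob=0.5,
                 diagnosis_threshold=50, validation_fraction=0.15,
                 random_state=None, verbose=False):
        self.growth_rate = growth_rate
        self.layers_per_block = layers_per_block
        self.initial_channels = initial_channels
        self.in_channels = in_channels
        self.multiscale = multiscale
        self.ms_kernels = ms_kernels
        self.ms_filters_per_branch = ms_filters_per_branch
        self.scse = scse
        self.scse_reduction = scse_reduction
        self.scse_placement = scse_placement
        self.dropout = dropout
        self.num_classes = num_classes
        self.loss = loss
        self.boundary_iterations = boundary_iterations
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.flip_prob = flip_prob
        self.diagnosis_threshold = diagnosis_threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            growth_rate=self.growth_rate, layers_per_block=tuple(self.layers_per_block),
            initial_channels=self.initial_channels, in_channels=self.in_channels,
            multiscale=self.multiscale, ms_kernels=tuple(self.ms_kernels),
            ms_filters_per_branch=self.ms_filters_per_branch, scse=self.scse,
            scse_reduction=self.scse_reduction, scse_placement=self.scse_placement,
            dropout=self.dropout, num_classes=self.num_classes)

    def _training_config(self, seed) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            max_epochs=self.max_epochs, patience=self.patience,
            batch_size=self.batch_size, flip_prob=self.flip_prob, loss=self.loss,
            boundary_iterations=self.boundary_iterations, seed=seed)

    @staticmethod
    def _check_xy(X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be shaped (n_images, height, width)")
        if y.shape != X.shape:
            raise ValueError("y must have the same shape as X")
        return X, y.astype(np.uint8)

    def _split_validation(self, X, y, rng):
        """Hold out a validation set stratified by lesion presence."""
        labels = np.array([m.any() for m in y])
        val_idx = []
        for cls in (False, True):
            idx = rng.permutation(np.nonzero(labels == cls)[0])
            n_val = max(1, int(round(self.validation_fraction * len(idx)))) if len(idx) else 0
            val_idx.extend(idx[:n_val])
        val_idx = np.array(sorted(val_idx))
        tr_idx = np.setdiff1d(np.arange(len(X)), val_idx)
        return (X[tr_idx], y[tr_idx]), (X[val_idx], y[val_idx])

    # ------------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train the network; returns self.

        When ``X_val``/``y_val`` are omitted a stratified
        ``validation_fraction`` of (X, y) is held out for early stopping.
        """
        X, y = self._check_xy(X, y)
        rng = np.random.default_rng(self.random_state)
        init_seed = int(rng.integers(0, 2 ** 31 - 1))
        train_seed = int(rng.integers(0, 2 ** 31 - 1))
        if X_val is None:
            (X_tr, y_tr), (X_va, y_va) = self._split_validation(X, y, rng)
        else:
            X_tr, y_tr = X, y
            X_va, y_va = self._check_xy(X_val, y_val)
        self.config_ = self._network_config()
        self.model_ = SegmentationNetwork(self.config_, seed=init_seed)
        self.n_parameters_ = count_parameters(self.model_)
        self.history_ = train(self.model_, (X_tr, y_tr), (X_va, y_va),
                              self._training_config(train_seed), verbose=self.verbose)
        self.n_epochs_ = len(self.history_)
        return self

    def predict(self, X):
        """Binary lesion masks, shaped like X."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        masks, _ = predict_masks(self.model_, X, batch_size=max(self.batch_size, 8))
        return masks

    def predict_proba(self, X):
        """Per-pixel class probabilities, shaped (n, num_classes, h, w)."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        out = []
        bs = max(self.batch_size, 8)
        for start in range(0, len(X), bs):
            out.append(self.model_.predict_proba(X[start:start + bs][:, None]))
        return np.concatenate(out)

    def score(self, X, y):
        """Mean lesion Dice (DSC1) over the given images."""
        X, y = self._check_xy(X, y)
        pred = self.predict(X)
        return dice(list(zip(pred, y)))["dsc1"]

    def diagnose(self, X):
        """Image-level calls from the pixel-count rule on predicted masks."""
        pred = self.predict(X)
        return [diagnose(m, self.diagnosis_threshold, image_id=str(i)).call
                for i, m in enumerate(pred)]
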