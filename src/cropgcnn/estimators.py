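"""scikit-learn style estimators wrapping the GCNN builders.

``GCNNClassifier`` fits a single-branch GCNN on one chosen color space;
``MultiBranchGCNNClassifier`` fits the fused multi-color-space model.
Both take RGB image batches of shape ``(n, h, w, 3)`` with values in
``[0, 1]`` (color conversion happens inside), follow the fit/predict
contract, and compose with sklearn model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import colorspace
from .colorspace import ImageBatch, convert_color, normalize_channels
from .model import GCNNConfig, build_gcnn, build_multibranch
from .nn import fit_network, predict_proba

__all__ = ["GCNNClassifier", "MultiBranchGCNNClassifier"]


def _validate_images(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError(
            f"X must be an RGB image batch of shape (n, h, w, 3); got {X.shape}"
        )
    if X.shape[1] % 4 or X.shape[2] % 4:
        raise ValueError("image height and width must be divisible by 4")
    return X


class _GCNNBase(BaseEstimator, ClassifierMixin):
    def _encode_labels(self, y):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        return y_idx

    def _train_config_kwargs(self):
        return dict(
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
        )

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = _validate_images(X)
        return predict_proba(self.model_, self._transform(X))

    def predict(self, X):
        idx = self.predict_proba(X).argmax(axis=1)
        return self.classes_[idx]


class GCNNClassifier(_GCNNBase):
    """Grouped-convolution CNN classifier on a single color space.

    Parameters
    ----------
    color_space : str, default "RGB"
        Input representation; one of the eight recognized spaces.
    stage1_filters, stage2_filters, groups, n_residual_blocks,
    dense_units, dropout_rate, skip_mode :
        Architecture hyperparameters, see :class:`cropgcnn.model.GCNNConfig`.
    optimizer, learning_rate, epochs, batch_size :
        Training hyperparameters.
    random_state : int
        Seeds weight initialization, shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique labels seen in ``fit``.
    model_ : GCNNModel
        The fitted network.
    history_ : list of dict
        Per-epoch train/validation loss and accuracy.
    """

    def __init__(
        self,
        color_space: str = "RGB",
        stage1_filters: int = 54,
        stage2_filters: int = 108,
        groups: int = 3,
        n_residual_blocks: int = 2,
        dense_units: tuple = (128, 64),
        dropout_rate: float = 0.5,
        skip_mode: str = "identity_or_project",
        optimizer: str = "adam",
        learning_rate: float = 1e-3,
        epochs: int = 10,
        batch_size: int = 32,
        random_state: int = 0,
    ):
        self.color_space = color_space
        self.stage1_filters = stage1_filters
        self.stage2_filters = stage2_filters
        self.groups = groups
        self.n_residual_blocks = n_residual_blocks
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.skip_mode = skip_mode
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _transform(self, X: np.ndarray) -> np.ndarray:
        batch = ImageBatch(X, space="RGB", normalized=False)
        out = normalize_channels(convert_color(batch, self.color_space))
        return out.pixels.astype(np.float32)

    def fit(self, X, y, X_val=None, y_val=None):
        if self.color_space not in colorspace.COLOR_SPACES:
            raise ValueError(f"unknown color_space {self.color_space!r}")
        X = _validate_images(X)
        y_idx = self._encode_labels(y)
        cfg = GCNNConfig(
            input_size=(X.shape[1], X.shape[2]),
            stage1_filters=self.stage1_filters,
            stage2_filters=self.stage2_filters,
            groups=self.groups,
            n_residual_blocks=self.n_residual_blocks,
            dense_units=tuple(self.dense_units),
            dropout_rate=self.dropout_rate,
            n_classes=len(self.classes_),
            skip_mode=self.skip_mode,
            seed=self.random_state,
        )
        self.model_ = build_gcnn(cfg)
        Xv = yv = None
        if X_val is not None:
            Xv = self._transform(_validate_images(X_val))
            yv = np.searchsorted(self.classes_, np.asarray(y_val))
        self.history_ = fit_network(
            self.model_, self._transform(X), y_idx, Xv, yv,
            **self._train_config_kwargs(),
        )
        return self


class MultiBranchGCNNClassifier(_GCNNBase):
    """Fused multi-color-space GCNN classifier.

    One independent GCNN branch per color space (the RGB input is
    expanded internally), fused either by feature concatenation under a
    fresh softmax head (``fusion="concat_features"``) or by averaging the
    branch probabilities (``fusion="average_probs"``).
    """

    def __init__(
        self,
        spaces: tuple = colorspace.EXPANSION_SPACES,
        fusion: str = "concat_features",
        stage1_filters: int = 54,
        stage2_filters: int = 108,
        groups: int = 3,
        n_residual_blocks: int = 2,
        dense_units: tuple = (128, 64),
        dropout_rate: float = 0.5,
        skip_mode: str = "identity_or_project",
        optimizer: str = "adam",
        learning_rate: float = 1e-3,
        epochs: int = 10,
        batch_size: int = 32,
        random_state: int = 0,
    ):
        self.spaces = spaces
        self.fusion = fusion
        self.stage1_filters = stage1_filters
        self.stage2_filters = stage2_filters
        self.groups = groups
        self.n_residual_blocks = n_residual_blocks
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.skip_mode = skip_mode
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _transform(self, X: np.ndarray) -> np.ndarray:
        # expansion happens inside the model's forward pass
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = _validate_images(X)
        y_idx = self._encode_labels(y)
        cfg = GCNNConfig(
            input_size=(X.shape[1], X.shape[2]),
            stage1_filters=self.stage1_filters,
            stage2_filters=self.stage2_filters,
            groups=self.groups,
            n_residual_blocks=self.n_residual_blocks,
            dense_units=tuple(self.dense_units),
            dropout_rate=self.dropout_rate,
            n_classes=len(self.classes_),
            skip_mode=self.skip_mode,
            seed=self.random_state,
        )
        self.model_ = build_multibranch(
            cfg, spaces=tuple(self.spaces), fusion=self.fusion
        )
        Xv = yv = None
        if X_val is not None:
            Xv = _validate_images(X_val)
            yv = np.searchsorted(self.classes_, np.asarray(y_val))
        self.history_ = fit_network(
            self.model_, X, y_idx, Xv, yv, **self._train_config_kwargs()
        )
        return self
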