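"""Posture classifiers: a static MLP and a family of LSTM sequence networks.

Both are scikit-learn-style estimators.  :class:`MLPPostureClassifier`
classifies single frames (10-feature vectors, or a selected subset) and
follows the optimized static architecture: three hidden layers of 10 tanh
("sigmoidal tangent") neurons and a 5-way softmax output, trained for at
most 1000 epochs with an internal 30% validation split for early stopping.

:class:`LSTMSequenceClassifier` performs sequence-to-sequence labeling:
one class per frame of a fixed-length window (60 frames = 2 s at 30 Hz),
mini-batches of 32 sequences, optional re-shuffling of the sequence order at
every epoch.  Variants cover the explored family (LSTM, LSTM2FC, 2LSTM,
BLSTM, 2BLSTM, 2BLSTM2D, 2BLSTM1D); the best-performing configuration is
2BLSTM2D with 125 and 100 hidden units and two 45% dropout layers.
Sentinel (999) frames are fed literally by default, as in deployment, where
tracker dropouts reach the classifier unfiltered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from . import nn
from .exceptions import ConfigError, SchemaError

__all__ = [
    "MLPPostureClassifier",
    "LSTMSequenceClassifier",
    "train_mlp",
    "train_lstm",
    "predict_frames",
    "kfold_validate",
]


def _apply_subset(X: np.ndarray, subset) -> np.ndarray:
    if subset is None:
        return X
    mask = np.asarray(subset, dtype=bool)
    if mask.sum() == 0:
        raise ConfigError("feature subset must select at least one feature")
    return X[..., mask]


class MLPPostureClassifier(BaseEstimator, ClassifierMixin):
    """Frame-wise posture classifier (multi-layer perceptron).

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Neurons per hidden layer; the optimized architecture uses (10, 10, 10).
    activation : str
        Hidden activation; ``"tanh"`` is the sigmoidal tangent.
    max_epochs : int
        Cap on training epochs (full passes over the training data).
    validation_fraction : float
        Fraction held out internally for early stopping.
    feature_subset : sequence of bool, optional
        Mask over input columns; applied in both fit and predict.
    random_state : int, optional
        Seeds initialization and the validation split; fixed seed + data
        gives identical fits.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (10, 10, 10),
        activation: str = "tanh",
        max_epochs: int = 1000,
        validation_fraction: float = 0.30,
        early_stopping: bool = True,
        n_iter_no_change: int = 10,
        learning_rate_init: float = 1e-3,
        feature_subset=None,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.early_stopping = early_stopping
        self.n_iter_no_change = n_iter_no_change
        self.learning_rate_init = learning_rate_init
        self.feature_subset = feature_subset
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise SchemaError(f"X must be (n_frames, n_features), got {X.shape}")
        Xs = _apply_subset(X, self.feature_subset)
        self._mlp_ = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation=self.activation,
            solver="adam",
            max_iter=self.max_epochs,
            early_stopping=self.early_stopping,
            validation_fraction=self.validation_fraction,
            n_iter_no_change=self.n_iter_no_change,
            learning_rate_init=self.learning_rate_init,
            random_state=self.random_state,
        )
        self._mlp_.fit(Xs, y)
        self.classes_ = self._mlp_.classes_
        self.n_features_in_ = X.shape[1]
        self.n_epochs_ = int(self._mlp_.n_iter_)
        return self

    def predict(self, X):
        check_is_fitted(self, "_mlp_")
        return self._mlp_.predict(_apply_subset(np.asarray(X, dtype=float), self.feature_subset))

    def predict_proba(self, X):
        check_is_fitted(self, "_mlp_")
        return self._mlp_.predict_proba(
            _apply_subset(np.asarray(X, dtype=float), self.feature_subset)
        )


def kfold_validate(
    estimator, X, y, k: int = 10, random_state: int | None = None
) -> np.ndarray:
    """Stratified k-fold validation accuracies (k = 10 by protocol)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
    scores = []
    for train_idx, val_idx in skf.split(X, y):
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        scores.append(float(np.mean(est.predict(X[val_idx]) == y[val_idx])))
    return np.asarray(scores)


def train_mlp(X, y, k_folds: int = 10, **params) -> tuple[MLPPostureClassifier, np.ndarray]:
    """Protocol-style MLP training: k-fold validation, then a fit on all data.

    Returns the final estimator and the per-fold validation accuracies.
    """
    model = MLPPostureClassifier(**params)
    fold_scores = kfold_validate(model, X, y, k=k_folds, random_state=params.get("random_state"))
    model.fit(X, y)
    return model, fold_scores


class LSTMSequenceClassifier(BaseEstimator, ClassifierMixin):
    """Sequence-to-sequence posture classifier (LSTM family).

    Consumes windows ``X`` of shape ``(n_sequences, T, n_features)`` with
    per-frame targets ``y`` of shape ``(n_sequences, T)`` and emits one
    label (and probability vector) per frame.

    Parameters
    ----------
    variant : str
        One of ``LSTM, LSTM2FC, 2LSTM, BLSTM, 2BLSTM, 2BLSTM2D, 2BLSTM1D``.
    hidden1, hidden2 : int
        Recurrent layer widths; ``hidden2`` defaults to ``hidden1 - 25``,
        the convention of the explored grid (75/100/125 first-layer units).
    dropout, dropout2 : float
        Dropout rates; ``dropout2`` defaults to ``dropout``.
    epochs, batch_size : int
        Training epochs and sequences per mini-batch (protocol: 50 and 32).
    shuffle_each_epoch : bool
        Re-permute the sequence order every epoch, changing mini-batch
        composition — this measurably helps generalization.
    standardize : bool
        Z-score features on the training set before the network (off by
        default so sentinel 999 inputs pass through literally).
    learning_rate, clip_norm : float
        Adam step size and global-norm gradient clip.
    random_state : int, optional
        Seeds initialization, shuffling and dropout; fixed seed + data gives
        a bit-identical trajectory.
    """

    def __init__(
        self,
        variant: str = "2BLSTM2D",
        hidden1: int = 125,
        hidden2: int | None = None,
        dropout: float = 0.45,
        dropout2: float | None = None,
        epochs: int = 50,
        batch_size: int = 32,
        shuffle_each_epoch: bool = True,
        standardize: bool = False,
        learning_rate: float = 3e-3,
        clip_norm: float = 1.0,
        feature_subset=None,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.dropout = dropout
        self.dropout2 = dropout2
        self.epochs = epochs
        self.batch_size = batch_size
        self.shuffle_each_epoch = shuffle_each_epoch
        self.standardize = standardize
        self.learning_rate = learning_rate
        self.clip_norm = clip_norm
        self.feature_subset = feature_subset
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = _apply_subset(np.asarray(X, dtype=np.float32), self.feature_subset)
        if X.ndim != 3:
            raise SchemaError(f"X must be (n_sequences, T, n_features), got {X.shape}")
        if hasattr(self, "_mean_") and self._mean_ is not None:
            X = (X - self._mean_) / self._sd_
        return X

    def fit(self, X, y):
        y = np.asarray(y)
        Xr = _apply_subset(np.asarray(X, dtype=np.float32), self.feature_subset)
        if Xr.ndim != 3 or y.shape != Xr.shape[:2]:
            raise SchemaError(
                f"shape mismatch: X {np.shape(X)} vs y {y.shape}; expected "
                "(n_sequences, T, n_features) and (n_sequences, T)"
            )
        if self.standardize:
            flat = Xr.reshape(-1, Xr.shape[-1])
            self._mean_ = flat.mean(axis=0)
            self._sd_ = np.maximum(flat.std(axis=0), 1e-6)
            Xr = (Xr - self._mean_) / self._sd_
        else:
            self._mean_ = None
            self._sd_ = None

        self.classes_ = np.unique(y)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.vectorize(class_index.get)(y).astype(np.int64)

        hidden2 = self.hidden2 if self.hidden2 is not None else max(self.hidden1 - 25, 1)
        rng = np.random.default_rng(self.random_state)
        self._net_ = nn.build_variant(
            self.variant,
            rng,
            input_dim=Xr.shape[2],
            n_classes=len(self.classes_),
            hidden1=self.hidden1,
            hidden2=hidden2,
            dropout=self.dropout,
            dropout2=self.dropout2,
        )
        opt = nn.Adam(self._net_, lr=self.learning_rate)
        n = len(Xr)
        log = []
        for epoch in range(self.epochs):
            order = rng.permutation(n) if self.shuffle_each_epoch else np.arange(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xr[idx], y_idx[idx]
                logits = self._net_.forward(xb, train=True, rng=rng)
                loss, dlogits = nn.softmax_cross_entropy(logits, yb)
                if not np.isfinite(loss):
                    raise ConfigError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                self._net_.backward(dlogits)
                nn.clip_global_norm(self._net_.params_grads(), self.clip_norm)
                opt.step()
                epoch_loss += loss * len(idx)
                correct += int((logits.argmax(axis=-1) == yb).sum())
            log.append(
                {
                    "epoch": epoch,
                    "loss": epoch_loss / n,
                    "accuracy": correct / (n * Xr.shape[1]),
                }
            )
        self.history_ = pd.DataFrame(log)
        self.n_features_in_ = np.shape(X)[-1]
        self.n_parameters_ = self._net_.n_parameters()
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_net_")
        X = self._prepare(X)
        rng = np.random.default_rng(0)  # unused: no stochastic layers at inference
        out = []
        for start in range(0, len(X), self.batch_size):
            logits = self._net_.forward(X[start : start + self.batch_size], train=False, rng=rng)
            out.append(nn.softmax(logits.astype(np.float64)))
        return np.concatenate(out) if out else np.empty((0,) + X.shape[1:2] + (len(self.classes_),))

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=-1)]

    def score(self, X, y):
        """Per-frame accuracy over all sequences."""
        y = np.asarray(y)
        return float(np.mean(self.predict(X) == y))


def train_lstm(X, y, **params) -> LSTMSequenceClassifier:
    """Fit an LSTM-family sequence classifier with the given configuration."""
    return LSTMSequenceClassifier(**params).fit(X, y)


def predict_frames(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame labels and class-probability vectors from either branch.

    For the MLP, ``X`` is ``(n_frames, n_features)``; for the sequence
    model, ``(n_sequences, T, n_features)``.  Probabilities sum to 1 per
    frame and the emitted label is their argmax.
    """
    probs = model.predict_proba(X)
    labels = model.classes_[probs.argmax(axis=-1)]
    return labels, probs
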