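"""Class-weighted feed-forward MLP classifier, implemented in numpy.

The classifier mirrors the compact architecture used for speech-derived
cognitive-impairment screening: an input layer sized to the 176 acoustic
descriptors, two hidden layers of 20 ReLU units, and a single sigmoid output,
trained by minibatch SGD (lr 0.01, exponential decay 0.95 per epoch, batch 32,
150 epochs) on a binary cross-entropy loss whose per-sample weights are
inversely proportional to class frequency and normalized by a factor of 2
(``w_c = N / (2 N_c)``), so the ~10% CU minority is not drowned out. No
dropout, batch normalization or weight decay is used; the small network is the
only capacity control.

Parameters are held as an explicit list of (weight, bias) pairs — the ``w`` on
which the federated aggregation operators act — rather than inside a framework
object, and the backward pass is written out so the gradient can be checked
against finite differences layer by layer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigError, DataError, NumericError
from .synthetic_data import CI, CU, FeatureTable

logger = logging.getLogger("fedcog.mlp")

DEFAULT_LAYER_SIZES = (176, 20, 20, 1)
DEFAULT_HIDDEN_SIZES = (20, 20, 1)
_EPS = 1e-12


# ---------------------------------------------------------------------------
# parameter tree


@dataclass(frozen=True)
class ModelParams:
    """Ordered (weight, bias) pairs; shapes chain input -> hidden -> output."""

    layers: tuple[tuple[np.ndarray, np.ndarray], ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigError("a model needs at least one layer")
        prev_out = None
        for i, (W, b) in enumerate(self.layers):
            if W.ndim != 2 or b.shape != (W.shape[1],):
                raise ConfigError(f"layer {i}: weight/bias shapes inconsistent")
            if prev_out is not None and W.shape[0] != prev_out:
                raise ConfigError(f"layer {i}: input dim {W.shape[0]} != {prev_out}")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise NumericError(f"layer {i}: non-finite parameters")
            prev_out = W.shape[1]

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.layers[0][0].shape[0],) + tuple(W.shape[1] for W, _ in self.layers)

    @property
    def n_params(self) -> int:
        return int(sum(W.size + b.size for W, b in self.layers))

    def flatten(self) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in self.layers])

    def copy(self) -> "ModelParams":
        return ModelParams(tuple((W.copy(), b.copy()) for W, b in self.layers))

    def map(self, fn) -> "ModelParams":
        return ModelParams(tuple((fn(W), fn(b)) for W, b in self.layers))

    def to_json(self) -> str:
        return json.dumps(
            [[W.tolist(), b.tolist()] for W, b in self.layers], separators=(",", ":")
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        layers = json.loads(text)
        return cls(
            tuple(
                (np.asarray(W, dtype=np.float64), np.asarray(b, dtype=np.float64))
                for W, b in layers
            )
        )


def init_params(layer_sizes=DEFAULT_LAYER_SIZES, seed: int = 0) -> ModelParams:
    """Glorot-uniform weights (±sqrt(6/(fan_in+fan_out))), zero biases."""
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2 or any(s <= 0 for s in sizes):
        raise ConfigError(f"need >=2 positive layer sizes, got {sizes}")
    rng = np.random.default_rng(seed)
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        layers.append((W, np.zeros(fan_out)))
    return ModelParams(tuple(layers))


# ---------------------------------------------------------------------------
# forward / loss / gradient


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_cached(params: ModelParams, X: np.ndarray):
    """Hidden ReLU activations plus output probabilities, keeping the
    pre-activations needed by the backward pass."""
    acts = [X]
    a = X
    n_layers = len(params.layers)
    for i, (W, b) in enumerate(params.layers):
        z = a @ W + b
        a = _sigmoid(z) if i == n_layers - 1 else np.maximum(z, 0.0)
        acts.append(a)
    return acts


def forward(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Predicted probability of CI for each row of X."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params.layer_sizes[0]:
        raise DataError(
            f"X must be (n, {params.layer_sizes[0]}), got {X.shape}"
        )
    return _forward_cached(params, X)[-1].ravel()


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights; both are 1 for balanced data."""

    weight_cu: float
    weight_ci: float

    def per_sample(self, labels: np.ndarray) -> np.ndarray:
        return np.where(labels == CI, self.weight_ci, self.weight_cu)


def class_weights(labels: np.ndarray) -> ClassWeights:
    """``w_c = N / (2 N_c)``: inverse class frequency normalized by 2."""
    labels = np.asarray(labels)
    n = labels.size
    n_ci = int(np.sum(labels == CI))
    n_cu = int(np.sum(labels == CU))
    if n_ci == 0 or n_cu == 0:
        raise DataError("class weights undefined: only one class present")
    return ClassWeights(weight_cu=n / (2.0 * n_cu), weight_ci=n / (2.0 * n_ci))


def weighted_bce(
    probs: np.ndarray, labels: np.ndarray, weights: ClassWeights | None = None
) -> float:
    """Mean over samples of ``w(y_i) * [-y_i log p_i - (1-y_i) log(1-p_i)]``,
    with probabilities clamped 1e-12 from the boundaries."""
    probs = np.asarray(probs, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if probs.shape != labels.shape:
        raise DataError(f"length mismatch: {probs.shape} vs {labels.shape}")
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    w = 1.0 if weights is None else weights.per_sample(labels)
    losses = -(labels * np.log(p) + (1 - labels) * np.log1p(-p))
    return float(np.mean(w * losses))


def loss_and_grad(
    params: ModelParams,
    X: np.ndarray,
    labels: np.ndarray,
    weights: ClassWeights | None = None,
) -> tuple[float, ModelParams]:
    """Weighted BCE and its analytic gradient w.r.t. every weight and bias."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    acts = _forward_cached(params, X)
    p = acts[-1].ravel()
    w = np.ones_like(y) if weights is None else weights.per_sample(labels)
    loss = weighted_bce(p, labels, weights)

    n = X.shape[0]
    # dL/dz_out for clamped BCE composed with sigmoid is w (p - y) / n
    delta = (w * (p - y) / n)[:, None]
    grads: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(len(params.layers) - 1, -1, -1):
        W, _ = params.layers[i]
        a_prev = acts[i]
        grads.append((a_prev.T @ delta, delta.sum(axis=0)))
        if i > 0:
            delta = (delta @ W.T) * (acts[i] > 0)
    grads.reverse()
    return loss, ModelParams(tuple(grads))


# ---------------------------------------------------------------------------
# standardization


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-scoring fitted on a node's training split.

    Raw eGeMAPS descriptors span several orders of magnitude, so each node
    standardizes with its own training statistics; the same transform is
    applied to that node's test data.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-8, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale

    def transform_table(self, table: FeatureTable) -> FeatureTable:
        return table.with_features(self.transform(table.features))

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(
            mean=np.asarray(d["mean"], dtype=np.float64),
            scale=np.asarray(d["scale"], dtype=np.float64),
        )


# ---------------------------------------------------------------------------
# training loop


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    lr_decay: float = 0.95  # applied per epoch
    batch_size: int = 32
    epochs: int = 150
    validation_fraction: float = 0.0  # optional monitoring hold-out, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ConfigError("lr_decay must lie in (0, 1]")
        if self.batch_size <= 0:
            raise ConfigError("batch_size must be positive")
        if self.epochs < 0:
            raise ConfigError("epochs must be nonnegative")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ConfigError("validation_fraction must lie in [0, 1)")


def learning_rate_at(config: TrainingConfig, epoch: int) -> float:
    """lr at (zero-based) cumulative epoch e: ``lr0 * decay^e``."""
    return config.learning_rate * config.lr_decay**epoch


def train_local(
    params: ModelParams,
    train: FeatureTable,
    config: TrainingConfig,
    *,
    epoch_offset: int = 0,
    rng: np.random.Generator | None = None,
    weights: ClassWeights | None = None,
) -> tuple[ModelParams, list[float]]:
    """Minibatch SGD on the class-weighted BCE; returns (params, epoch losses).

    Class weights are computed once from the node's training labels (not per
    batch) and applied per sample in every batch. ``epoch_offset`` continues
    the exponential learning-rate schedule from a cumulative epoch count, so a
    federated client resumes the same lr trajectory a centrally trained model
    would see. ``epochs=0`` returns the parameters unchanged.

    With ``validation_fraction > 0`` that share of rows is held out before
    training and its loss is logged per epoch — monitoring only, no early
    stopping.
    """
    if train.n_samples == 0:
        raise DataError("cannot train on an empty table")
    X = train.features
    y = train.labels
    if weights is None:
        weights = class_weights(y)  # raises DataError on single-class input
    if rng is None:
        rng = np.random.default_rng(config.seed)

    val_X = val_y = None
    if config.validation_fraction > 0:
        n_val = int(np.floor(config.validation_fraction * len(y)))
        if 0 < n_val < len(y):
            order = rng.permutation(len(y))
            val_X, val_y = X[order[:n_val]], y[order[:n_val]]
            X, y = X[order[n_val:]], y[order[n_val:]]

    current = params.copy()
    losses: list[float] = []
    n = X.shape[0]
    for e in range(config.epochs):
        lr = learning_rate_at(config, epoch_offset + e)
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grad = loss_and_grad(current, X[idx], y[idx], weights)
            if not np.isfinite(loss):
                raise NumericError(f"non-finite loss at epoch {epoch_offset + e}")
            current = ModelParams(
                tuple(
                    (W - lr * gW, b - lr * gb)
                    for (W, b), (gW, gb) in zip(current.layers, grad.layers)
                )
            )
            batch_losses.append(loss)
        losses.append(float(np.mean(batch_losses)))
        if val_X is not None:
            val_loss = weighted_bce(_forward_cached(current, val_X)[-1].ravel(),
                                    val_y, weights)
            logger.debug("epoch %d val_loss %.6f", epoch_offset + e, val_loss)
    return current, losses


def make_training_config(**overrides) -> TrainingConfig:
    return replace(TrainingConfig(), **overrides)
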