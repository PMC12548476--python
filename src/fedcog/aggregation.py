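"""Federated aggregation operators: FedAvg, IDA, and a plain mean baseline.

FedAvg forms the sample-size-weighted average of client parameters,

    w_{t+1} = sum_k (n_k / n) w_k^{t+1},      n = sum_k n_k,

trusting data-rich clients more. IDA (inverse-distance aggregation) instead
weights each client inversely to how far its model sits from the unweighted
average of the round's local models,

    alpha_k = (1/Z) (||w_avg - w_k||_1 + eps)^{-1},   w_{t+1} = sum_k alpha_k w_k^{t+1},

down-weighting outlier updates. The l1 distance is taken over the fully
flattened parameter tree (weights and biases). Note a structural fact that
matters for two-institution federations: with exactly two clients each model
is equidistant from their midpoint, so IDA always degenerates to the uniform
average regardless of eps — the plain-mean aggregator is included so this is
observable in reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DataError, NumericError
from .mlp import ModelParams

DEFAULT_EPSILON = 1e-8

AGGREGATION_METHODS = ("fedavg", "ida", "mean")


@dataclass(frozen=True)
class ClientUpdate:
    """One client's post-training parameters plus its training sample count."""

    params: ModelParams
    n_samples: int
    client_id: str = ""

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError(f"n_samples must be >= 1, got {self.n_samples}")


@dataclass(frozen=True)
class AggregationWeights:
    """Normalized per-client mixing coefficients (and, for IDA, distances)."""

    alphas: tuple[float, ...]
    distances: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.alphas) - 1.0) > 1e-12 or any(a < 0 for a in self.alphas):
            raise NumericError("aggregation weights must be nonnegative and sum to 1")


def _check_updates(items: list) -> None:
    if not items:
        raise DataError("nothing to aggregate: empty client list")
    shapes = {tuple((W.shape, b.shape) for W, b in p.layers) for p in items}
    if len(shapes) != 1:
        raise DataError("client parameter shapes differ")


def _combine(params_list: list[ModelParams], alphas: np.ndarray) -> ModelParams:
    layers = []
    for i in range(len(params_list[0].layers)):
        W = sum(a * p.layers[i][0] for a, p in zip(alphas, params_list))
        b = sum(a * p.layers[i][1] for a, p in zip(alphas, params_list))
        layers.append((np.asarray(W), np.asarray(b)))
    return ModelParams(tuple(layers))


def fedavg(updates: list[ClientUpdate]) -> ModelParams:
    """Exact sample-size-weighted mean of the client parameters."""
    _check_updates([u.params for u in updates])
    n = np.array([u.n_samples for u in updates], dtype=np.float64)
    return _combine([u.params for u in updates], n / n.sum())


def ida_weights(
    local_params: list[ModelParams], epsilon: float = DEFAULT_EPSILON
) -> AggregationWeights:
    """Inverse-l1-distance weights relative to the unweighted average model."""
    _check_updates(local_params)
    if epsilon <= 0:
        raise ConfigError("epsilon must be positive")
    flat = np.stack([p.flatten() for p in local_params])
    if not np.isfinite(flat).all():
        raise NumericError("non-finite client parameters")
    avg = flat.mean(axis=0)
    d = np.abs(avg - flat).sum(axis=1)
    inv = 1.0 / (d + epsilon)
    alphas = inv / inv.sum()
    return AggregationWeights(alphas=tuple(alphas.tolist()), distances=tuple(d.tolist()))


def ida_aggregate(
    updates: list[ClientUpdate], epsilon: float = DEFAULT_EPSILON
) -> ModelParams:
    """IDA-weighted sum of client parameters."""
    w = ida_weights([u.params for u in updates], epsilon)
    return _combine([u.params for u in updates], np.asarray(w.alphas))


def mean_aggregate(updates: list[ClientUpdate]) -> ModelParams:
    """Unweighted entrywise mean (baseline)."""
    _check_updates([u.params for u in updates])
    k = len(updates)
    return _combine([u.params for u in updates], np.full(k, 1.0 / k))


def aggregate(
    updates: list[ClientUpdate],
    method: str = "fedavg",
    epsilon: float = DEFAULT_EPSILON,
) -> ModelParams:
    """Dispatch to one of the aggregation methods by name."""
    if method == "fedavg":
        return fedavg(updates)
    if method == "ida":
        return ida_aggregate(updates, epsilon)
    if method == "mean":
        return mean_aggregate(updates)
    raise ConfigError(f"unknown aggregation method {method!r}; use one of {AGGREGATION_METHODS}")
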