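"""Round-based federated orchestration and the local-only baseline condition.

Two training conditions are compared per scenario. In the *local* condition
each institution trains its own MLP on its own data and never communicates; in
the *federated* condition a global model is trained by repeating
broadcast -> local SGD -> aggregation for a fixed number of communication
rounds. The total local-epoch budget (rounds x local epochs per round,
default 150 x 1) equals the 150 epochs the local condition uses, and the
exponential learning-rate schedule advances with the *cumulative* epoch count,
so both conditions see the identical lr trajectory.

Each client standardizes features with its own training statistics and weights
its loss by its own class frequencies. Per-client shuffle generators are
seeded identically (they advance independently), which keeps the orchestration
bit-reproducible and makes aggregation of identical clients an exact fixed
point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import DEFAULT_EPSILON, ClientUpdate, aggregate, ida_weights
from .exceptions import ConfigError, DataError, NumericError
from .mlp import (
    DEFAULT_HIDDEN_SIZES,
    ModelParams,
    Standardizer,
    TrainingConfig,
    class_weights,
    forward,
    init_params,
    train_local,
)
from .partition import NodeDataset


@dataclass(frozen=True)
class FederationConfig:
    rounds: int = 150
    local_epochs_per_round: int = 1
    aggregator: str = "fedavg"
    epsilon: float = DEFAULT_EPSILON
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds <= 0 or self.local_epochs_per_round <= 0:
            raise ConfigError("rounds and local_epochs_per_round must be positive")

    @property
    def total_local_epochs(self) -> int:
        return self.rounds * self.local_epochs_per_round


@dataclass(frozen=True)
class RoundLog:
    """Audit record of one communication round."""

    round_index: int
    client_losses: dict[str, float]
    client_n: dict[str, int]
    alphas: dict[str, float] | None
    distances: dict[str, float] | None
    global_l1_change: float

    def to_dict(self) -> dict:
        return {
            "round": self.round_index,
            "client_losses": self.client_losses,
            "client_n": self.client_n,
            "alphas": self.alphas,
            "distances": self.distances,
            "global_l1_change": self.global_l1_change,
        }


@dataclass(frozen=True)
class LocalResult:
    """Outcome of independently training one node (params or a failure)."""

    node_id: str
    params: ModelParams | None
    scaler: Standardizer | None
    losses: list[float]
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _node_scalers(nodes: list[NodeDataset]) -> dict[str, Standardizer]:
    return {nd.node_id: Standardizer.fit(nd.train.features) for nd in nodes}


def _resolve_layer_sizes(
    layer_sizes: tuple[int, ...] | None, nodes: list[NodeDataset]
) -> tuple[int, ...]:
    """Default architecture: input width from the data, then 20-20-1."""
    if layer_sizes is not None:
        return tuple(layer_sizes)
    return (nodes[0].train.n_features,) + DEFAULT_HIDDEN_SIZES


def run_local_condition(
    nodes: list[NodeDataset],
    training: TrainingConfig,
    layer_sizes: tuple[int, ...] | None = None,
) -> dict[str, LocalResult]:
    """Train one independent model per node; a failing node (e.g. single-class
    training data) is reported in its own result without aborting the rest."""
    if not nodes:
        raise DataError("no nodes to train")
    layer_sizes = _resolve_layer_sizes(layer_sizes, nodes)
    results: dict[str, LocalResult] = {}
    for nd in nodes:
        scaler = Standardizer.fit(nd.train.features)
        try:
            params = init_params(layer_sizes, seed=training.seed)
            rng = np.random.default_rng(training.seed)
            params, losses = train_local(
                params, scaler.transform_table(nd.train), training, rng=rng
            )
            results[nd.node_id] = LocalResult(nd.node_id, params, scaler, losses)
        except (DataError, NumericError) as exc:
            results[nd.node_id] = LocalResult(nd.node_id, None, scaler, [], str(exc))
    return results


@dataclass(frozen=True)
class FederatedResult:
    global_params: ModelParams
    scalers: dict[str, Standardizer]
    round_logs: list[RoundLog]


def run_federated_condition(
    nodes: list[NodeDataset],
    config: FederationConfig,
    layer_sizes: tuple[int, ...] | None = None,
) -> FederatedResult:
    """Round-based federated training of one shared global model.

    Each round the current global parameters are broadcast to every client,
    each client runs ``local_epochs_per_round`` epochs of SGD (continuing the
    global lr schedule at its cumulative epoch count, reusing its fixed class
    weights), and the resulting updates are aggregated with the configured
    method. The final global model is what gets evaluated on every node's
    test set.
    """
    if not nodes:
        raise DataError("no nodes to federate")
    layer_sizes = _resolve_layer_sizes(layer_sizes, nodes)
    scalers = _node_scalers(nodes)
    std_trains = {nd.node_id: scalers[nd.node_id].transform_table(nd.train) for nd in nodes}
    node_weights = {nd.node_id: class_weights(nd.train.labels) for nd in nodes}

    global_params = init_params(layer_sizes, seed=config.seed)
    # identical per-client seeding: clients with identical data follow
    # identical trajectories, making the aggregate an exact fixed point
    client_rngs = {nd.node_id: np.random.default_rng(config.training.seed) for nd in nodes}

    local_cfg = TrainingConfig(
        learning_rate=config.training.learning_rate,
        lr_decay=config.training.lr_decay,
        batch_size=config.training.batch_size,
        epochs=config.local_epochs_per_round,
        seed=config.training.seed,
    )

    logs: list[RoundLog] = []
    for r in range(config.rounds):
        updates: list[ClientUpdate] = []
        losses: dict[str, float] = {}
        for nd in nodes:
            params, epoch_losses = train_local(
                global_params.copy(),
                std_trains[nd.node_id],
                local_cfg,
                epoch_offset=r * config.local_epochs_per_round,
                rng=client_rngs[nd.node_id],
                weights=node_weights[nd.node_id],
            )
            updates.append(
                ClientUpdate(params=params, n_samples=nd.train.n_samples, client_id=nd.node_id)
            )
            losses[nd.node_id] = float(np.mean(epoch_losses)) if epoch_losses else float("nan")

        alphas = distances = None
        if config.aggregator == "ida":
            w = ida_weights([u.params for u in updates], config.epsilon)
            alphas = {u.client_id: a for u, a in zip(updates, w.alphas)}
            distances = {u.client_id: d for u, d in zip(updates, w.distances)}

        new_global = aggregate(updates, config.aggregator, config.epsilon)
        flat_new = new_global.flatten()
        if not np.isfinite(flat_new).all():
            raise NumericError(f"non-finite global parameters after round {r}")
        l1_change = float(np.abs(flat_new - global_params.flatten()).sum())
        global_params = new_global
        logs.append(
            RoundLog(
                round_index=r,
                client_losses=losses,
                client_n={u.client_id: u.n_samples for u in updates},
                alphas=alphas,
                distances=distances,
                global_l1_change=l1_change,
            )
        )
    return FederatedResult(global_params=global_params, scalers=scalers, round_logs=logs)


def predict_on_node(
    params: ModelParams, scaler: Standardizer, table
) -> np.ndarray:
    """Probabilities of CI on a node's (raw) table using that node's scaler."""
    return forward(params, scaler.transform(table.features))
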