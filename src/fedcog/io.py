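"""CSV/JSON interchange, experiment configuration, and the end-to-end driver.

Feature tables travel as plain CSV (columns ``sample_id, site, label,
f001...``; labels written as the strings CU/CI), metrics and manifests as
JSON, and per-round federation logs as JSON lines. ``run_experiment`` chains
generate -> partition -> split -> both training conditions -> evaluation and
writes every artifact plus a manifest sufficient to re-run bit-identically:
all stage seeds are derived deterministically from one master seed via
``numpy.random.SeedSequence(master_seed).generate_state(4) % 2**31`` in the
fixed order (generator, partition, split, training).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import MetricsReport, evaluate
from .exceptions import ConfigError, DataError
from .federation import (
    FederatedResult,
    FederationConfig,
    LocalResult,
    predict_on_node,
    run_federated_condition,
    run_local_condition,
)
from .mlp import TrainingConfig
from .partition import (
    DEFAULT_TRAIN_FRACTION,
    NodeDataset,
    ScenarioSpec,
    get_scenario,
    make_node_datasets,
    partition_cohort,
)
from .synthetic_data import (
    CI,
    CU,
    LABEL_CODES,
    LABEL_NAMES,
    FeatureTable,
    GeneratorConfig,
    generate_cohort,
)

logger = logging.getLogger("fedcog")

RESERVED_COLUMNS = ("sample_id", "site", "label")


# ---------------------------------------------------------------------------
# feature-table CSV


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV with header sample_id, site, label, f001...; labels as CU/CI."""
    df = pd.DataFrame(table.features, columns=list(table.columns))
    df.insert(0, "label", [LABEL_NAMES[int(l)] for l in table.labels])
    site = table.site if table.site is not None else [""] * table.n_samples
    df.insert(0, "site", site)
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False, encoding="utf-8")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Parse and validate a feature-table CSV (round-trip of the writer)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "site": str, "label": str})
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty file") from None
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    feature_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not feature_cols:
        raise DataError(f"{path}: no feature columns found")
    if df.empty:
        raise DataError(f"{path}: no data rows")

    bad = ~df["label"].isin(LABEL_CODES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(
            f"{path}: unknown label {df['label'].iloc[row]!r} at row {row + 2} "
            f"(expected one of {sorted(LABEL_CODES)})"
        )
    features = np.empty((len(df), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=np.float64)
        if np.isnan(vals).any():
            row = int(np.flatnonzero(np.isnan(vals))[0])
            raise DataError(
                f"{path}: non-numeric or missing value in column {col!r} at row {row + 2}"
            )
        features[:, j] = vals
    site = None
    if "site" in df.columns:
        site = df["site"].fillna("").to_numpy(dtype=object)
    return FeatureTable(
        features=features,
        labels=np.array([LABEL_CODES[l] for l in df["label"]], dtype=np.int64),
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        site=site,
        columns=tuple(feature_cols),
    )


# ---------------------------------------------------------------------------
# experiment configuration


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from the master seed (documented order)."""
    state = np.random.SeedSequence(master_seed).generate_state(4)
    names = ("generator", "partition", "split", "training")
    return {name: int(s % 2**31) for name, s in zip(names, state)}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run one scenario end to end."""

    generator: GeneratorConfig
    scenario: ScenarioSpec
    training: TrainingConfig = field(default_factory=TrainingConfig)
    federation: FederationConfig = field(default_factory=FederationConfig)
    layer_sizes: tuple[int, ...] | None = None  # None: input width from data, then 20-20-1
    train_fraction: float = DEFAULT_TRAIN_FRACTION
    out_dir: str = "fedcog_run"
    master_seed: int = 0
    threshold: float = 0.5

    def with_derived_seeds(self) -> "ExperimentConfig":
        seeds = derive_stage_seeds(self.master_seed)
        training = dataclasses.replace(self.training, seed=seeds["training"])
        return dataclasses.replace(
            self,
            generator=dataclasses.replace(self.generator, seed=seeds["generator"]),
            training=training,
            federation=dataclasses.replace(self.federation, training=training,
                                           seed=seeds["training"]),
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        try:
            gen = GeneratorConfig(**raw.get("generator", {"n_samples": 2239}))
            scen = raw.get("scenario", "scenario1")
            if isinstance(scen, str):
                scenario = get_scenario(scen)
            else:
                scenario = ScenarioSpec(
                    name=scen.get("name", "custom"),
                    node_fractions=tuple(scen["node_fractions"]),
                    node_ci_fraction=tuple(scen["node_ci_fraction"]),
                )
            training = TrainingConfig(**raw.get("training", {}))
            fed_raw = dict(raw.get("federation", {}))
            federation = FederationConfig(training=training, **fed_raw)
            return cls(
                generator=gen,
                scenario=scenario,
                training=training,
                federation=federation,
                layer_sizes=(
                    tuple(raw["layer_sizes"]) if raw.get("layer_sizes") else None
                ),
                train_fraction=float(raw.get("train_fraction", DEFAULT_TRAIN_FRACTION)),
                out_dir=raw.get("out_dir", "fedcog_run"),
                master_seed=int(raw.get("master_seed", 0)),
                threshold=float(raw.get("threshold", 0.5)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid experiment config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def snapshot(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "generator": enc(self.generator),
            "scenario": enc(self.scenario),
            "training": enc(self.training),
            "federation": enc(self.federation),
            "layer_sizes": None if self.layer_sizes is None else list(self.layer_sizes),
            "train_fraction": self.train_fraction,
            "out_dir": self.out_dir,
            "master_seed": self.master_seed,
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class RunManifest:
    config: dict
    derived_seeds: dict[str, int]
    artifacts: dict[str, str]
    started_at: str
    elapsed_seconds: float
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# end-to-end driver


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _counts_manifest(nodes: list[NodeDataset]) -> dict:
    out = {}
    for nd in nodes:
        out[nd.node_id] = {
            "total": nd.train.n_samples + nd.test.n_samples,
            "train": {"total": nd.train.n_samples, **nd.train.class_counts()},
            "test": {"total": nd.test.n_samples, **nd.test.class_counts()},
        }
    return out


def evaluate_conditions(
    nodes: list[NodeDataset],
    local: dict[str, LocalResult],
    federated: FederatedResult,
    threshold: float = 0.5,
    scenario: str = "",
) -> list[MetricsReport]:
    """Full evaluation grid: every local model on every node's test set (the
    cross-evaluation design) and the single global model on each test set."""
    reports: list[MetricsReport] = []
    for model_node, res in local.items():
        if not res.ok:
            continue
        for nd in nodes:
            probs = predict_on_node(res.params, res.scaler, nd.test)
            reports.append(
                evaluate(
                    probs,
                    nd.test.labels,
                    threshold,
                    node=nd.node_id,
                    condition=f"local[{model_node}]",
                    scenario=scenario,
                )
            )
    for nd in nodes:
        probs = predict_on_node(
            federated.global_params, federated.scalers[nd.node_id], nd.test
        )
        reports.append(
            evaluate(
                probs,
                nd.test.labels,
                threshold,
                node=nd.node_id,
                condition="federated",
                scenario=scenario,
            )
        )
    return reports


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    """Tabular report: one row per (scenario, condition, evaluated node),
    metrics rounded to 2 decimals as in standard reporting; full precision
    stays in the JSON artifacts."""
    rows = []
    for r in reports:
        d = r.to_dict(ndigits=2)
        cm = d.pop("confusion")
        d.pop("undefined")
        d.update({f"cm_{k}": v for k, v in cm.items()})
        rows.append(d)
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> RunManifest:
    """Generate a cohort, partition it, train both conditions, evaluate, and
    persist all artifacts under ``config.out_dir``."""
    t0 = time.time()
    started = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    cfg = config.with_derived_seeds()
    seeds = derive_stage_seeds(cfg.master_seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "generate"
    try:
        logger.info("stage=generate seed=%d", seeds["generator"])
        cohort = generate_cohort(cfg.generator)

        stage = "partition"
        logger.info("stage=partition scenario=%s seed=%d", cfg.scenario.name, seeds["partition"])
        node_tables = partition_cohort(cohort, cfg.scenario, seed=seeds["partition"])

        stage = "split"
        logger.info("stage=split seed=%d", seeds["split"])
        nodes = make_node_datasets(node_tables, cfg.train_fraction, seed=seeds["split"])
        for nd in nodes:
            for split_name, t in (("train", nd.train), ("test", nd.test)):
                p = out / f"{nd.node_id}_{split_name}.csv"
                write_feature_table(t, p)
                artifacts[f"{nd.node_id}_{split_name}"] = str(p)
        counts_path = out / "partition_counts.json"
        _json_dump(_counts_manifest(nodes), counts_path)
        artifacts["partition_counts"] = str(counts_path)

        stage = "train-local"
        logger.info("stage=train-local seed=%d", seeds["training"])
        local = run_local_condition(nodes, cfg.training, cfg.layer_sizes)

        stage = "train-federated"
        logger.info(
            "stage=train-federated aggregator=%s rounds=%d",
            cfg.federation.aggregator,
            cfg.federation.rounds,
        )
        federated = run_federated_condition(nodes, cfg.federation, cfg.layer_sizes)
        rounds_path = out / "rounds.jsonl"
        with open(rounds_path, "w", encoding="utf-8") as fh:
            for log in federated.round_logs:
                fh.write(json.dumps(log.to_dict(), sort_keys=True) + "\n")
        artifacts["round_logs"] = str(rounds_path)

        stage = "evaluate"
        reports = evaluate_conditions(
            nodes, local, federated, cfg.threshold, scenario=cfg.scenario.name
        )
        metrics_payload = {
            "scenario": cfg.scenario.name,
            "reports": [r.to_dict() for r in reports],
            "local_failures": {
                nid: res.error for nid, res in local.items() if not res.ok
            },
        }
        metrics_path = out / "metrics.json"
        _json_dump(metrics_payload, metrics_path)
        artifacts["metrics"] = str(metrics_path)
        table_path = out / "metrics.csv"
        reports_to_frame(reports).to_csv(table_path, index=False)
        artifacts["metrics_table"] = str(table_path)
        confusion_path = out / "confusion.json"
        _json_dump(
            [
                {"scenario": r.scenario, "condition": r.condition, "node": r.node,
                 **r.confusion_matrix.to_dict()}
                for r in reports
            ],
            confusion_path,
        )
        artifacts["confusion"] = str(confusion_path)
    except Exception as exc:
        partial = out / "failure.json"
        _json_dump({"stage": stage, "error": str(exc), "artifacts": artifacts}, partial)
        raise

    manifest = RunManifest(
        config=cfg.snapshot(),
        derived_seeds=seeds,
        artifacts=artifacts,
        started_at=started,
        elapsed_seconds=round(time.time() - t0, 3),
    )
    _json_dump(manifest.to_dict(), out / "manifest.json")
    return manifest
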