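"""Virtual-institution partitioning and per-node train/test splitting.

A single cohort is divided between two (or more) simulated institutions
("nodes") according to a scenario preset that fixes each node's share of the
total cases (quantity skew) and each node's CI fraction (label skew). Three
presets mirror the heterogeneity conditions studied for a two-institution
memory-clinic federation:

* scenario1 — equal halves, both nodes ~90% CI (the homogeneous baseline);
* scenario2 — 10% vs 90% of the cases, same ~90% CI mix (quantity skew);
* scenario3 — a CI-heavy node (~97% CI) against a more balanced node
  (~78% CI) in roughly a 63/37 size ratio (label skew).

Rounding conventions are exact and deliberate: node k receives
``floor(fraction_k * N)`` cases for every node but the last, which takes the
remainder; within a node the CI quota is ``round(ci_fraction * size)``, again
with the last node absorbing the remaining members of both class pools. The
train split takes ``floor(0.7 * N)`` rows, allocated across classes by largest
remainder. These conventions reproduce the published two-institution split
tables exactly (1,119 -> 783/336; 1,120 -> 784/336; 223 -> 156/67;
2,016 -> 1,411/605 at N = 2,239).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DataError
from .synthetic_data import CI, CU, FeatureTable

DEFAULT_TRAIN_FRACTION = 0.70


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ScenarioSpec:
    """Per-node share of the cohort and per-node CI composition."""

    name: str
    node_fractions: tuple[float, ...]
    node_ci_fraction: tuple[float, ...]

    def __post_init__(self) -> None:
        fracs = tuple(float(f) for f in self.node_fractions)
        cis = tuple(float(c) for c in self.node_ci_fraction)
        if len(fracs) != len(cis) or not fracs:
            raise ConfigError("node_fractions and node_ci_fraction must align")
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError(f"node fractions must be nonnegative and sum to 1, got {fracs}")
        if any(not 0.0 <= c <= 1.0 for c in cis):
            raise ConfigError(f"node CI fractions must lie in [0, 1], got {cis}")
        object.__setattr__(self, "node_fractions", fracs)
        object.__setattr__(self, "node_ci_fraction", cis)

    @property
    def n_nodes(self) -> int:
        return len(self.node_fractions)


# Scenario 3's published node totals (1,395 and 831) sum to 2,226, not to the
# 2,239-participant cohort; the preset keeps their ratio, so partitioning a
# 2,226-row cohort reproduces the printed totals exactly.
SCENARIOS: dict[str, ScenarioSpec] = {
    "scenario1": ScenarioSpec("scenario1", (0.5, 0.5), (0.9, 0.9)),
    "scenario2": ScenarioSpec("scenario2", (0.1, 0.9), (0.9, 0.9)),
    "scenario3": ScenarioSpec("scenario3", (1395 / 2226, 831 / 2226), (0.97, 0.78)),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


@dataclass(frozen=True)
class NodeDataset:
    """One institution's disjoint train/test portion of the cohort."""

    node_id: str
    train: FeatureTable
    test: FeatureTable

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.train.sample_ids, self.test.sample_ids)
        if overlap.size:
            raise DataError(f"{self.node_id}: train/test overlap on {overlap[:5]}")


def partition_cohort(
    table: FeatureTable, spec: ScenarioSpec, seed: int
) -> list[FeatureTable]:
    """Assign every cohort row to exactly one node.

    Node sizes follow the floor-then-remainder rule; class quotas are filled by
    seeded sampling without replacement from the CU and CI pools, the last node
    receiving whatever remains of both pools (its realized class mix therefore
    deviates from the preset by at most a fraction of a percent). Raises
    DataError naming the node and class when a quota exhausts its pool.
    """
    rng = np.random.default_rng(seed)
    n = table.n_samples
    if n == 0:
        raise DataError("cannot partition an empty cohort")

    sizes = [int(np.floor(f * n)) for f in spec.node_fractions[:-1]]
    sizes.append(n - sum(sizes))
    if sizes[-1] < 0:
        raise ConfigError("node fractions allocate more rows than the cohort holds")

    pools = {
        CI: rng.permutation(np.flatnonzero(table.labels == CI)),
        CU: rng.permutation(np.flatnonzero(table.labels == CU)),
    }
    cursor = {CI: 0, CU: 0}

    nodes: list[FeatureTable] = []
    for k, size in enumerate(sizes):
        last = k == len(sizes) - 1
        if last:
            take = {c: len(pools[c]) - cursor[c] for c in (CI, CU)}
            if take[CI] + take[CU] != size:  # pragma: no cover - sizes partition n
                raise DataError(f"node {k + 1}: remainder does not match node size")
        else:
            n_ci = _round_half_up(spec.node_ci_fraction[k] * size)
            take = {CI: n_ci, CU: size - n_ci}
        idx_parts = []
        for cls in (CI, CU):
            avail = len(pools[cls]) - cursor[cls]
            if take[cls] > avail:
                raise DataError(
                    f"node {k + 1}: quota of {take[cls]} "
                    f"{'CI' if cls == CI else 'CU'} cases exceeds the {avail} remaining"
                )
            idx_parts.append(pools[cls][cursor[cls] : cursor[cls] + take[cls]])
            cursor[cls] += take[cls]
        idx = np.concatenate(idx_parts) if idx_parts else np.empty(0, dtype=np.intp)
        rng.shuffle(idx)
        nodes.append(table.subset(idx))
    return nodes


def train_test_split(
    table: FeatureTable,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Class-stratified split with ``|train| = floor(train_fraction * N)``.

    Per-class training counts are the floors of ``train_fraction * N_c`` with
    the leftover rows assigned by largest fractional remainder, so the total
    always equals the floor of the overall fraction. Emits a warning (not an
    error) if a class present in the table ends up absent from either side.
    """
    if table.n_samples == 0:
        raise DataError("cannot split an empty table")
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError(f"train_fraction must lie in (0, 1), got {train_fraction}")

    rng = np.random.default_rng(seed)
    n_train = int(np.floor(train_fraction * table.n_samples))

    classes = [c for c in (CI, CU) if np.any(table.labels == c)]
    ideal = {c: train_fraction * np.sum(table.labels == c) for c in classes}
    counts = {c: int(np.floor(ideal[c])) for c in classes}
    leftover = n_train - sum(counts.values())
    # ties broken toward the larger class, then CI, deterministically
    order = sorted(
        classes,
        key=lambda c: (ideal[c] - counts[c], np.sum(table.labels == c), c),
        reverse=True,
    )
    for c in order[:leftover]:
        counts[c] += 1

    train_idx, test_idx = [], []
    for c in classes:
        members = rng.permutation(np.flatnonzero(table.labels == c))
        train_idx.append(members[: counts[c]])
        test_idx.append(members[counts[c] :])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))

    train, test = table.subset(train_idx), table.subset(test_idx)
    for c in classes:
        name = "CI" if c == CI else "CU"
        if not np.any(train.labels == c):
            warnings.warn(f"class {name} has no training members", stacklevel=2)
        if not np.any(test.labels == c):
            warnings.warn(f"class {name} has no test members", stacklevel=2)
    return train, test


def make_node_datasets(
    node_tables: list[FeatureTable],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> list[NodeDataset]:
    """Split each node's table 70/30, seeding each node's shuffle independently."""
    nodes = []
    for k, t in enumerate(node_tables):
        if t.n_samples == 0:
            raise DataError(f"node{k + 1} received no samples and cannot be split")
        train, test = train_test_split(t, train_fraction, seed=seed + k)
        nodes.append(NodeDataset(node_id=f"node{k + 1}", train=train, test=test))
    return nodes
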