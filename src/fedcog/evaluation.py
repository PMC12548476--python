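"""Confusion matrices and the six-metric classification panel.

CI (the merged MCI + dementia group) is the positive class throughout; with a
~90% CI prevalence this is what makes precision near 1 and specificity (CU
recognition) the hard, informative number. The panel is balanced accuracy,
precision, sensitivity, specificity, F1 and ROC AUC. Ratios with zero
denominators are reported as NaN and flagged by name rather than silently
coerced to 0, and the AUC uses the rank-based (Mann-Whitney) estimator with
midranks, so ties contribute 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import DataError
from .synthetic_data import CI

DEFAULT_THRESHOLD = 0.5

METRIC_NAMES = (
    "balanced_accuracy",
    "precision",
    "sensitivity",
    "specificity",
    "f1",
    "auc",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with CI as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def confusion(
    probs: np.ndarray, labels: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> ConfusionMatrix:
    """Threshold the scores (predict CI iff prob >= threshold) and count."""
    probs = np.asarray(probs, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if probs.shape != labels.shape:
        raise DataError(f"length mismatch: {probs.shape} vs {labels.shape}")
    if probs.size == 0:
        raise DataError("cannot evaluate an empty prediction vector")
    pred = probs >= threshold
    pos = labels == CI
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: the probability a random positive outranks a random
    negative, ties counting one half. NaN when a class is absent."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise DataError(f"length mismatch: {scores.shape} vs {labels.shape}")
    pos = labels == CI
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)  # midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class MetricsReport:
    """The six-metric panel for one (node, condition) cell, plus provenance.

    Metrics whose defining ratio has a zero denominator are NaN and listed in
    ``undefined``.
    """

    balanced_accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    confusion_matrix: ConfusionMatrix
    node: str = ""
    condition: str = ""
    scenario: str = ""
    undefined: tuple[str, ...] = field(default=())

    def to_dict(self, ndigits: int | None = None) -> dict:
        vals = {m: getattr(self, m) for m in METRIC_NAMES}
        if ndigits is not None:
            vals = {
                m: (round(v, ndigits) if not math.isnan(v) else None)
                for m, v in vals.items()
            }
        else:
            vals = {m: (None if math.isnan(v) else v) for m, v in vals.items()}
        return {
            "scenario": self.scenario,
            "condition": self.condition,
            "node": self.node,
            **vals,
            "confusion": self.confusion_matrix.to_dict(),
            "undefined": list(self.undefined),
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metrics(
    cm: ConfusionMatrix,
    probs: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    *,
    node: str = "",
    condition: str = "",
    scenario: str = "",
) -> MetricsReport:
    """Assemble the panel from a confusion matrix and (for AUC) raw scores.

    balanced accuracy is exactly (sensitivity + specificity) / 2; F1 is the
    harmonic mean of precision and sensitivity. AUC is NaN unless both scores
    and labels are supplied with both classes present.
    """
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    balanced = (sensitivity + specificity) / 2.0
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    if probs is not None and labels is not None:
        auc = auc_score(probs, labels)
    else:
        auc = math.nan
    report = MetricsReport(
        balanced_accuracy=balanced,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        auc=auc,
        confusion_matrix=cm,
        node=node,
        condition=condition,
        scenario=scenario,
        undefined=tuple(
            m
            for m in METRIC_NAMES
            if math.isnan(
                {"balanced_accuracy": balanced, "precision": precision,
                 "sensitivity": sensitivity, "specificity": specificity,
                 "f1": f1, "auc": auc}[m]
            )
        ),
    )
    return report


def evaluate(
    probs: np.ndarray,
    labels: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    **tags,
) -> MetricsReport:
    """Convenience wrapper: confusion matrix + panel in one call."""
    cm = confusion(probs, labels, threshold)
    return metrics(cm, probs, labels, **tags)
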