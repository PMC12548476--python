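"""Synthetic acoustic-feature cohorts for federated-learning experiments.

Real speech-biomarker datasets for cognitive-impairment detection are held by
single memory clinics and are not publicly deposited, so every downstream
stage of this package is exercised on synthetic cohorts that mimic the
statistical shape of such data: one row per participant, 176 continuous
acoustic descriptors (two speech tasks x 88 eGeMAPS-style variables), and a
binary diagnosis label with a heavily imbalanced prevalence (~9.9% cognitively
unimpaired, CU, vs ~90.1% cognitively impaired, CI).

The generative model is deliberately simple: class-conditional multivariate
Gaussians with identity covariance. Non-informative features are standard
normal in both classes; a chosen subset of "informative" features has its mean
shifted by ``effect_size`` in the CI class. Under this model the
Bayes-optimal ROC AUC has the closed form ``Phi(d * sqrt(m) / sqrt(2))`` for
``m`` informative features with per-feature shift ``d``, which anchors the
test suite to an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .exceptions import ConfigError, DataError

CU, CI = 0, 1
LABEL_NAMES = {CU: "CU", CI: "CI"}
LABEL_CODES = {"CU": CU, "CI": CI}

#: two tasks x 88 eGeMAPS-style descriptors
DEFAULT_N_FEATURES = 176
#: CU fraction of the emulated memory-clinic cohort
DEFAULT_CU_PREVALENCE = 0.099


def feature_names(n_features: int) -> tuple[str, ...]:
    """Column names ``f001..fNNN``; for the canonical 176-feature layout the
    first and second halves carry ``task1_`` / ``task2_`` prefixes echoing the
    picture-description and verbal-fluency tasks (cosmetic only)."""
    width = max(3, len(str(n_features)))
    names = [f"f{i + 1:0{width}d}" for i in range(n_features)]
    if n_features == DEFAULT_N_FEATURES:
        half = n_features // 2
        names = [("task1_" if i < half else "task2_") + n for i, n in enumerate(names)]
    return tuple(names)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    effect_size is the standardized mean shift of each informative feature in
    the CI class; n_informative counts how many features carry it. site_shift,
    if positive, adds a constant offset to every feature of a random half of
    the cohort (a crude covariate shift between two recording sites).
    label_noise flips each label independently after feature generation.
    """

    n_samples: int
    n_features: int = DEFAULT_N_FEATURES
    cu_prevalence: float = DEFAULT_CU_PREVALENCE
    effect_size: float = 0.573  # Bayes AUC ~ 0.90 with the default 10 informative features
    n_informative: int | None = None  # None: min(10, n_features)
    site_shift: float = 0.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError(f"n_samples must be positive, got {self.n_samples}")
        if self.n_features <= 0:
            raise ConfigError(f"n_features must be positive, got {self.n_features}")
        if not 0.0 < self.cu_prevalence < 1.0:
            raise ConfigError(
                f"cu_prevalence must lie in (0, 1), got {self.cu_prevalence}"
            )
        if self.n_informative is None:
            object.__setattr__(self, "n_informative", min(10, self.n_features))
        if self.n_informative < 0 or self.n_informative > self.n_features:
            raise ConfigError(
                f"n_informative must lie in [0, n_features={self.n_features}], "
                f"got {self.n_informative}"
            )
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be nonnegative, got {self.effect_size}")
        if self.site_shift < 0:
            raise ConfigError(f"site_shift must be nonnegative, got {self.site_shift}")
        if not 0.0 <= self.label_noise < 0.5:
            raise ConfigError(
                f"label_noise must lie in [0, 0.5), got {self.label_noise}"
            )


@dataclass(frozen=True)
class FeatureTable:
    """An in-memory labeled feature table: one row per participant.

    labels are coded CU=0, CI=1 (CI, the merged MCI+dementia group, is the
    positive class throughout the package).
    """

    features: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray
    site: np.ndarray | None = None
    columns: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int64)
        ids = np.asarray(self.sample_ids, dtype=object)
        if features.ndim != 2:
            raise DataError("features must be a 2-D matrix")
        n = features.shape[0]
        if labels.shape != (n,) or ids.shape != (n,):
            raise DataError("features, labels and sample_ids must agree in length")
        if n and not np.isfinite(features).all():
            raise DataError("features contain non-finite values")
        if n and not np.isin(labels, (CU, CI)).all():
            raise DataError("labels must be coded CU=0 / CI=1")
        if len(np.unique(ids)) != n:
            raise DataError("sample_ids must be unique")
        if self.site is not None:
            site = np.asarray(self.site, dtype=object)
            if site.shape != (n,):
                raise DataError("site must align with rows")
            object.__setattr__(self, "site", site)
        cols = tuple(self.columns) if self.columns else feature_names(features.shape[1])
        if len(cols) != features.shape[1]:
            raise DataError("column names must match the feature count")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "columns", cols)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[str, int]:
        return {
            "CU": int(np.sum(self.labels == CU)),
            "CI": int(np.sum(self.labels == CI)),
        }

    def subset(self, indices: np.ndarray) -> "FeatureTable":
        idx = np.asarray(indices, dtype=np.intp)
        return FeatureTable(
            features=self.features[idx],
            labels=self.labels[idx],
            sample_ids=self.sample_ids[idx],
            site=None if self.site is None else self.site[idx],
            columns=self.columns,
        )

    def with_features(self, features: np.ndarray) -> "FeatureTable":
        return replace(self, features=np.asarray(features, dtype=np.float64))


def bayes_auc(effect_size: float, n_informative: int) -> float:
    """Bayes-optimal AUC of the generator's two-Gaussian model.

    The optimal score is the linear discriminant x . (mu_CI - mu_CU); its
    class-conditional difference is N(d^2 m, 2 d^2 m), hence
    AUC = Phi(d sqrt(m) / sqrt(2)).
    """
    return float(norm.cdf(effect_size * np.sqrt(n_informative) / np.sqrt(2.0)))


def generate_cohort(config: GeneratorConfig) -> FeatureTable:
    """Draw one synthetic cohort.

    The realized CU count is the deterministic quota
    ``round(n_samples * cu_prevalence)`` (before label noise), so fixture
    arithmetic — e.g. 2,239 participants at 9.9% CU giving 222 CU rows — is
    reproducible without Bernoulli jitter. Identical configs (the seed is part
    of the config) produce bit-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n_cu = _round_half_up(n * config.cu_prevalence)
    if n_cu == 0 or n_cu == n:
        raise DataError(
            f"prevalence {config.cu_prevalence} leaves a single class at n={n}"
        )
    labels = np.concatenate(
        [np.full(n_cu, CU, dtype=np.int64), np.full(n - n_cu, CI, dtype=np.int64)]
    )
    rng.shuffle(labels)

    features = rng.standard_normal((n, config.n_features))
    if config.n_informative and config.effect_size:
        features[labels == CI, : config.n_informative] += config.effect_size

    if config.site_shift > 0:
        shifted = rng.random(n) < 0.5
        features[shifted] += config.site_shift
        site = np.where(shifted, "siteB", "siteA").astype(object)
    else:
        site = np.full(n, "siteA", dtype=object)

    if config.label_noise > 0:
        flips = rng.random(n) < config.label_noise
        labels = np.where(flips, 1 - labels, labels)

    width = len(str(n))
    ids = np.array([f"S{i + 1:0{width}d}" for i in range(n)], dtype=object)
    return FeatureTable(
        features=features,
        labels=labels,
        sample_ids=ids,
        site=site,
        columns=feature_names(config.n_features),
    )
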