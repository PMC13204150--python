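"""Core dataset container, CSV I/O, run configuration, and RNG management.

All randomness in the package flows through :func:`rng_stream`: each pipeline
stage derives its own independent generator from the master seed and a stage
tag, so a full run is bit-reproducible and stages stay independently
reproducible when re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class LabeledDataset:
    """A samples x features numeric table with binary class labels.

    Labels are encoded ``{0, 1}`` internally (0 = healthy, 1 = case); formula
    boundaries that need signed or one-hot targets adapt at the call site.
    """

    features: np.ndarray          # (n_samples, n_features) float
    labels: np.ndarray            # (n_samples,) int in {0, 1}
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D table")
        n, p = self.features.shape
        if self.labels.shape != (n,):
            raise ValidationError(
                f"label vector length {self.labels.shape} does not match "
                f"sample count {n}")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise ValidationError(f"labels must take values in {{0,1}}, got {sorted(uniq)}")
        self.labels = self.labels.astype(int)
        if not np.all(np.isfinite(self.features)):
            i, j = np.argwhere(~np.isfinite(self.features))[0]
            raise ValidationError(
                f"non-finite feature value at row {i}, column "
                f"'{self.feature_names[j] if self.feature_names else j}'")
        if len(self.feature_names) != p:
            raise ValidationError("feature_names length must equal feature count")
        if len(set(self.feature_names)) != p:
            raise ValidationError("feature_names must be unique")
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        rows = np.asarray(rows)
        return LabeledDataset(
            self.features[rows], self.labels[rows],
            list(self.feature_names), [self.sample_ids[i] for i in rows])


def load_dataset(path, label_column: str = "label") -> LabeledDataset:
    """Load a CSV feature table (header row, one label column) into a dataset.

    Non-numeric feature cells, non-finite values, and non-binary labels are
    rejected with an error naming the offending row and column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValidationError(f"label column '{label_column}' not found in {path}")
    feature_cols = [c for c in df.columns if c != label_column]
    for col in feature_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric or non-finite value at row {row}, column '{col}'")
        df[col] = values
    labels = pd.to_numeric(df[label_column], errors="coerce")
    if labels.isna().any() or not set(labels.unique()) <= {0, 1}:
        bad = labels.isna() | ~labels.isin([0, 1])
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"non-binary label at row {row}, column '{label_column}'")
    return LabeledDataset(
        features=df[feature_cols].to_numpy(dtype=float),
        labels=labels.to_numpy(dtype=int),
        feature_names=[str(c) for c in feature_cols],
        sample_ids=[str(i) for i in df.index],
    )


def write_dataset(dataset: LabeledDataset, path, label_column: str = "label") -> None:
    """Write a dataset as CSV (features + one label column, header row)."""
    df = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    df[label_column] = dataset.labels
    df.to_csv(path, index=False)


def _tag_int(tag: str) -> int:
    digest = hashlib.sha256(tag.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def rng_stream(master_seed: int, stage_tag: str) -> np.random.Generator:
    """Deterministic, independent random stream per (master seed, stage tag).

    The same pair always yields an identical generator; different tags yield
    statistically independent streams via :class:`numpy.random.SeedSequence`.
    """
    if master_seed < 0:
        raise ValidationError("master seed must be a non-negative integer")
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), _tag_int(stage_tag)]))


@dataclass
class RunConfig:
    """One pipeline configuration: extractor, selector, classifier, CV, seed."""

    extractor: str = "pca"
    extractor_params: dict = field(default_factory=dict)
    selector: str = "gsa_pso"
    selector_params: dict = field(default_factory=dict)
    classifier: str = "elm_adaboost"
    classifier_params: dict = field(default_factory=dict)
    n_folds: int = 10
    n_repeats: int = 5
    seed: int = 0

    def validate(self) -> "RunConfig":
        from .extraction import EXTRACTORS
        from .selection import SELECTORS
        from .classifiers import CLASSIFIERS
        if self.extractor not in EXTRACTORS:
            raise ValidationError(f"unknown extractor '{self.extractor}'")
        if self.selector not in SELECTORS:
            raise ValidationError(f"unknown selector '{self.selector}'")
        if self.classifier not in CLASSIFIERS:
            raise ValidationError(f"unknown classifier '{self.classifier}'")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValidationError("seed must be a non-negative integer")
        return self

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload).validate()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)
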