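"""Cohort container, feature schema, delimited-text I/O and stratified splitting.

A cohort is a plain tabular dataset: one row per patient encounter, a fixed
ordered feature schema (demographic, blood and urine features), a binary
label (1 = disease-positive minority class, 0 = control) and a per-row
provenance flag distinguishing real from synthetically generated rows.
All downstream stages (cluster-based undersampling, augmentation, stacking)
consume and produce :class:`CohortTable` objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CATEGORIES = ("demographic", "blood", "urine")
DTYPES = ("continuous", "count", "categorical")

REAL = "real"
SYNTHETIC = "synthetic"


class SchemaError(ValueError):
    """A file or table does not conform to the declared feature schema."""


class ValidationError(ValueError):
    """Row-level contents violate the cohort contract (e.g. non-binary label)."""


@dataclass(frozen=True)
class Feature:
    name: str
    category: str  # demographic | blood | urine
    dtype: str     # continuous | count | categorical

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(f"unknown feature category {self.category!r}")
        if self.dtype not in DTYPES:
            raise SchemaError(f"unknown feature dtype {self.dtype!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature declaration plus the label column name."""

    features: tuple[Feature, ...]
    label_name: str = "kd"

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        if self.label_name in names:
            raise SchemaError("label column must not appear among features")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def dtype_of(self, name: str) -> str:
        for f in self.features:
            if f.name == name:
                return f.dtype
        raise KeyError(name)

    def indices_of_dtype(self, dtype: str) -> list[int]:
        return [i for i, f in enumerate(self.features) if f.dtype == dtype]

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for f in self.features:
            out[f.category] += 1
        return out

    # --- sidecar serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label_name": self.label_name,
            "features": [
                {"name": f.name, "category": f.category, "dtype": f.dtype}
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        feats = tuple(Feature(**f) for f in d["features"])
        return cls(features=feats, label_name=d.get("label_name", "kd"))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def kd_schema() -> FeatureSchema:
    """The bundled 22-feature screening schema: 3 demographic, 17 blood, 2 urine.

    Demographics are sex, age (years) and month of visit; blood features are
    routine CBC/differential and chemistry values (WBC, platelet count, CRP,
    liver transaminases, ...); urine features are urinary white cells and a
    pyuria flag. Categorical features are integer-coded; no one-hot expansion
    is performed (the downstream learners are tree ensembles).
    """
    d, b, u = "demographic", "blood", "urine"
    feats = (
        Feature("Sex", d, "categorical"),
        Feature("Age", d, "continuous"),
        Feature("Month", d, "categorical"),
        Feature("WBC", b, "continuous"),
        Feature("RBC", b, "continuous"),
        Feature("Hemoglobin", b, "continuous"),
        Feature("Hematocrit", b, "continuous"),
        Feature("Platelet", b, "continuous"),
        Feature("CRP", b, "continuous"),
        Feature("AST", b, "continuous"),
        Feature("ALT", b, "continuous"),
        Feature("Band", b, "count"),
        Feature("Segment", b, "continuous"),
        Feature("Lymphocyte", b, "continuous"),
        Feature("Monocyte", b, "continuous"),
        Feature("Eosinophil", b, "continuous"),
        Feature("Basophil", b, "continuous"),
        Feature("ESR", b, "continuous"),
        Feature("Albumin", b, "continuous"),
        Feature("Sodium", b, "continuous"),
        Feature("UWBC", u, "count"),
        Feature("Pyuria", u, "categorical"),
    )
    schema = FeatureSchema(features=feats, label_name="kd")
    assert schema.category_counts() == {"demographic": 3, "blood": 17, "urine": 2}
    return schema


@dataclass
class CohortTable:
    """Numeric cohort: values (n_rows x n_features), binary labels, provenance.

    ``values`` column order follows ``schema.features``. Categorical features
    are integer-coded floats. ``provenance`` entries are ``"real"`` or
    ``"synthetic"``.
    """

    schema: FeatureSchema
    values: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValidationError("labels length must match row count")
        if self.values.shape[1] != self.schema.n_features:
            raise SchemaError(
                f"value matrix has {self.values.shape[1]} columns, "
                f"schema declares {self.schema.n_features}"
            )
        bad = np.flatnonzero(~np.isin(self.labels, (0, 1)))
        if bad.size:
            raise ValidationError(f"non-binary label at row {bad[0]}")
        if self.provenance is None:
            self.provenance = np.full(self.n_rows, REAL, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape[0] != self.n_rows:
                raise ValidationError("provenance length must match row count")
            bad_p = set(self.provenance) - {REAL, SYNTHETIC}
            if bad_p:
                raise ValidationError(f"unknown provenance values {sorted(bad_p)}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.n_rows - self.labels.sum())

    def subset(self, idx: Sequence[int] | np.ndarray) -> "CohortTable":
        idx = np.asarray(idx, dtype=int)
        return CohortTable(
            schema=self.schema,
            values=self.values[idx],
            labels=self.labels[idx],
            provenance=self.provenance[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.schema.names)
        df[self.schema.label_name] = self.labels
        if np.any(self.provenance == SYNTHETIC):
            df["provenance"] = self.provenance
        return df

    @staticmethod
    def concat(tables: Iterable["CohortTable"]) -> "CohortTable":
        tables = list(tables)
        schema = tables[0].schema
        return CohortTable(
            schema=schema,
            values=np.vstack([t.values for t in tables]),
            labels=np.concatenate([t.labels for t in tables]),
            provenance=np.concatenate([t.provenance for t in tables]),
        )


@dataclass(frozen=True)
class ClassRatio:
    n_pos: int
    n_neg: int
    neg_per_pos: float
    defined: bool  # False when n_pos == 0

    def display(self) -> str:
        if not self.defined:
            return "undefined (no positives)"
        return f"1:{self.neg_per_pos:.0f}"


def read_cohort(
    path: str | Path,
    schema: FeatureSchema,
    impute_median: bool = False,
) -> CohortTable:
    """Read a comma-delimited cohort file under the given schema.

    The header must contain every schema feature name and the label column.
    Missing values are rejected unless ``impute_median`` is set, in which case
    per-column medians fill the gaps (external-data convenience only).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in schema.names + [schema.label_name] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column {missing[0]!r} in {path}")
    feat = df[schema.names].astype(float)
    if feat.isna().any().any():
        if impute_median:
            feat = feat.fillna(feat.median())
        else:
            row = int(np.flatnonzero(feat.isna().any(axis=1))[0])
            raise ValidationError(f"missing feature value at row {row}")
    raw_labels = df[schema.label_name]
    bad = ~raw_labels.isin([0, 1])
    if bad.any():
        raise ValidationError(
            f"non-binary label value at row {int(np.flatnonzero(bad)[0])}"
        )
    if "provenance" in df.columns:
        prov = df["provenance"].to_numpy(dtype=object)
    else:
        prov = None
    return CohortTable(
        schema=schema,
        values=feat.to_numpy(),
        labels=raw_labels.to_numpy(dtype=int),
        provenance=prov,
    )


def write_cohort(table: CohortTable, path: str | Path) -> Path:
    """Write a cohort as CSV (header = schema order + label).

    A ``provenance`` column is emitted only when at least one row is synthetic,
    so purely real cohorts round-trip to files indistinguishable from raw
    exports. ``read_cohort`` inverts this exactly for finite inputs.
    """
    path = Path(path)
    # 17 significant digits guarantee bit-exact float64 round-trips
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def split_cohort(
    table: CohortTable, test_fraction: float, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Stratified train/test split, deterministic for a fixed seed.

    Each class is split independently; the test side takes
    ``ceil(n_class * test_fraction)`` rows of each class, which reproduces
    an 8:2 split of 1,142 positives / 73,499 negatives as 229 / 14,700.
    Row order within each part follows the original table.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(table.labels == cls)
        if cls_idx.size < 2:
            raise ValueError(
                f"class {cls} has {cls_idx.size} member(s); cannot stratify"
            )
        n_test = math.ceil(cls_idx.size * test_fraction)
        perm = rng.permutation(cls_idx.size)
        test_idx.append(cls_idx[perm[:n_test]])
        train_idx.append(cls_idx[perm[n_test:]])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return table.subset(tr), table.subset(te)


def class_ratio(table: CohortTable) -> ClassRatio:
    """Positive/negative counts and negatives-per-positive ratio.

    A cohort with no positives returns ``defined=False`` and a NaN ratio
    rather than raising: pure-negative subsets arise routinely inside the
    cluster filter.
    """
    if table.n_rows == 0:
        raise ValidationError("empty table")
    n_pos, n_neg = table.n_pos, table.n_neg
    if n_pos == 0:
        return ClassRatio(n_pos, n_neg, float("nan"), defined=False)
    return ClassRatio(n_pos, n_neg, n_neg / n_pos, defined=True)
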