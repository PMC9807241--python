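"""Tabular data loading, zero-value cleaning and SMOTE class balancing.

The reference schema is the Pima Indians Diabetes layout: eight numeric
features plus a binary ``Outcome`` column.  In that dataset a literal ``0``
in Glucose, BloodPressure or BMI is a missing-value code, so cleaning means
profiling and dropping rows with zeros in those columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

PIMA_FEATURES: tuple[str, ...] = (
    "Pregnancies",
    "Glucose",
    "BloodPressure",
    "SkinThickness",
    "Insulin",
    "BMI",
    "DiabetesPedigreeFunction",
    "Age",
)
PIMA_OUTCOME = "Outcome"

#: columns whose zeros are missing-value codes in the reference schema
DEFAULT_ZERO_FEATURES: tuple[str, ...] = ("Glucose", "BloodPressure", "BMI")


@dataclasses.dataclass(frozen=True)
class RecordTable:
    """An n x d numeric feature matrix with binary labels.

    The universal data carrier of the package: every stage (cleaning, LDA,
    learners, cascade, CV) consumes and produces one of these.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if labels.shape != (features.shape[0],):
            raise ValueError(
                f"labels length {labels.shape} does not match "
                f"{features.shape[0]} records"
            )
        if features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must equal feature count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if np.isnan(features).any():
            raise ValueError("features contain missing values")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.features[:, j]

    def take(self, indices: np.ndarray) -> "RecordTable":
        return RecordTable(
            self.features[indices], self.labels[indices], self.feature_names
        )

    def to_dataframe(self, outcome_name: str = PIMA_OUTCOME) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df[outcome_name] = self.labels
        return df


@dataclasses.dataclass(frozen=True)
class CleaningReport:
    """Result of profiling zero-valued cells in selected columns."""

    zero_counts: dict[str, int]
    rows_before: int
    rows_after: int
    dropped_indices: tuple[int, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "zero_counts": self.zero_counts,
                "rows_before": self.rows_before,
                "rows_after": self.rows_after,
                "dropped_indices": list(self.dropped_indices),
            },
            indent=2,
        )


@dataclasses.dataclass(frozen=True)
class BalanceResult:
    """A class-balanced table produced by SMOTE oversampling."""

    table: RecordTable
    n_synthetic: int
    seed: int
    k_neighbors: int


def load_table(
    path: str | Path,
    feature_names: Sequence[str] = PIMA_FEATURES,
    outcome_name: str = PIMA_OUTCOME,
) -> RecordTable:
    """Load a CSV with a header row into a :class:`RecordTable`.

    The header must be exactly ``feature_names`` followed by
    ``outcome_name``; every cell must parse as a number and the outcome
    must be 0/1.  Violations raise ``ValueError`` naming the offending
    row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, header=0, skipinitialspace=True)
    expected = list(feature_names) + [outcome_name]
    if list(df.columns) != expected:
        raise ValueError(
            f"header mismatch in {path}: expected {expected}, "
            f"found {list(df.columns)}"
        )
    for col in expected:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric or missing cell at data row {row}, "
                f"column {col!r} in {path}"
            )
        df[col] = parsed
    outcome = df[outcome_name].to_numpy()
    if not np.isin(outcome, (0, 1)).all():
        row = int(np.flatnonzero(~np.isin(outcome, (0, 1)))[0])
        raise ValueError(
            f"non-binary outcome at data row {row}, column {outcome_name!r}"
        )
    return RecordTable(
        df[list(feature_names)].to_numpy(dtype=float),
        outcome.astype(int),
        tuple(feature_names),
    )


def save_table(
    table: RecordTable, path: str | Path, outcome_name: str = PIMA_OUTCOME
) -> None:
    """Write a RecordTable back to CSV with the same header layout."""
    table.to_dataframe(outcome_name).to_csv(path, index=False)


def profile_zeros(
    table: RecordTable, features: Iterable[str] = DEFAULT_ZERO_FEATURES
) -> CleaningReport:
    """Count exact-zero cells per profiled column and list affected rows.

    "Zero" means exactly 0.0 after numeric parse; no epsilon tolerance,
    because the zero is a missing-value code rather than a measurement.
    """
    features = list(features)
    zero_counts: dict[str, int] = {}
    dropped = np.zeros(table.n, dtype=bool)
    for name in features:
        col = table.column(name)  # raises KeyError on unknown feature
        is_zero = col == 0.0
        zero_counts[name] = int(is_zero.sum())
        dropped |= is_zero
    dropped_indices = tuple(int(i) for i in np.flatnonzero(dropped))
    return CleaningReport(
        zero_counts=zero_counts,
        rows_before=table.n,
        rows_after=table.n - len(dropped_indices),
        dropped_indices=dropped_indices,
    )


def drop_zero_rows(
    table: RecordTable, features: Iterable[str] = DEFAULT_ZERO_FEATURES
) -> tuple[RecordTable, CleaningReport]:
    """Remove every record with a zero in any profiled feature."""
    report = profile_zeros(table, features)
    if report.rows_after == 0:
        raise ValueError("cleaning would drop every record")
    keep = np.ones(table.n, dtype=bool)
    keep[list(report.dropped_indices)] = False
    return table.take(np.flatnonzero(keep)), report


def smote_balance(
    table: RecordTable, k_neighbors: int = 5, seed: int = 0
) -> BalanceResult:
    """Equalise class counts by SMOTE minority oversampling.

    Each synthetic record is ``x_i + u * (x_nn - x_i)`` with
    ``u ~ Uniform(0, 1)`` and ``x_nn`` one of the ``k_neighbors`` nearest
    minority neighbours of ``x_i`` under Euclidean distance.  Original
    records are preserved verbatim and the result is deterministic for a
    given seed.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be a positive integer")
    counts = np.bincount(table.labels, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present")
    minority = int(np.argmin(counts))
    deficit = int(abs(counts[0] - counts[1]))
    if deficit == 0:
        return BalanceResult(table, 0, seed, k_neighbors)
    minority_idx = np.flatnonzero(table.labels == minority)
    if len(minority_idx) <= k_neighbors:
        raise ValueError(
            f"minority class has {len(minority_idx)} records; "
            f"needs more than k_neighbors={k_neighbors}"
        )
    X_min = table.features[minority_idx]
    dist = cdist(X_min, X_min)
    np.fill_diagonal(dist, np.inf)
    # column-stable argsort so neighbour choice is reproducible
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k_neighbors]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(minority_idx), size=deficit)
    pick = rng.integers(0, k_neighbors, size=deficit)
    u = rng.random(deficit)
    x_i = X_min[base]
    x_nn = X_min[neighbours[base, pick]]
    synthetic = x_i + u[:, None] * (x_nn - x_i)

    features = np.vstack([table.features, synthetic])
    labels = np.concatenate(
        [table.labels, np.full(deficit, minority, dtype=int)]
    )
    return BalanceResult(
        RecordTable(features, labels, table.feature_names),
        deficit,
        seed,
        k_neighbors,
    )
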