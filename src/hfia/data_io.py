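"""Reading labelled expression matrices and writing selection reports.

Datasets are delimited text (CSV/TSV) with a header row, samples in rows
and features in columns by default; a ``transpose`` flag covers the
feature-major dumps common for microarray text files.  Class labels come
either from a named column of the matrix file or from a sidecar file with
one label per line.  Labels are opaque hashable tokens — never assumed
numeric or ordered.
"""

from __future__ import annotations

import dataclasses
import json
import numbers
import os
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "SelectionResult", "read_dataset", "write_report"]


@dataclass(frozen=True)
class LabeledDataset:
    """A labelled sample-by-feature numeric matrix: the antigen environment.

    Attributes
    ----------
    matrix
        ``(n, q)`` float array, no missing or non-finite values.
    labels
        ``n`` class identifiers (any hashable tokens), ``c >= 2`` distinct.
    feature_names
        ``q`` strings; generated ``f0..f{q-1}`` if absent.
    sample_ids
        ``n`` strings, optional.
    """

    matrix: np.ndarray
    labels: tuple
    feature_names: tuple[str, ...]
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got ndim={matrix.ndim}")
        if not np.all(np.isfinite(matrix)):
            bad = np.argwhere(~np.isfinite(matrix))[0]
            raise ValueError(
                f"matrix contains a non-finite value at row {bad[0]}, column {bad[1]}"
            )
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != matrix.shape[0]:
            raise ValueError(
                f"label count {len(self.labels)} does not match "
                f"sample count {matrix.shape[0]}"
            )
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if len(self.feature_names) != matrix.shape[1]:
            raise ValueError(
                f"feature-name count {len(self.feature_names)} does not match "
                f"feature count {matrix.shape[1]}"
            )
        if self.sample_ids is not None:
            object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
            if len(self.sample_ids) != matrix.shape[0]:
                raise ValueError("sample_ids length does not match sample count")
        if self.n_classes < 2:
            raise ValueError(
                f"need at least 2 distinct classes, got {self.n_classes}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> tuple:
        """Distinct labels in a fixed deterministic order (sorted by repr)."""
        return tuple(sorted(set(self.labels), key=lambda c: (str(c), repr(c))))

    @property
    def n_classes(self) -> int:
        return len(set(self.labels))

    def encoded_labels(self) -> np.ndarray:
        """Labels as integers ``0..c-1`` under the fixed class order."""
        index = {c: i for i, c in enumerate(self.classes)}
        return np.fromiter((index[l] for l in self.labels), dtype=np.intp,
                           count=self.n_samples)

    def restrict_features(self, columns: Sequence[int]) -> "LabeledDataset":
        cols = np.asarray(columns, dtype=np.intp)
        return LabeledDataset(
            matrix=self.matrix[:, cols],
            labels=self.labels,
            feature_names=tuple(self.feature_names[i] for i in cols),
            sample_ids=self.sample_ids,
        )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a feature-selection run.

    ``reduction_rate`` is ``1 - n_selected / q`` over the *original*
    feature space; ``best_fitness_trajectory`` holds the best fitness seen
    after initialization and after each of the ``Tmax`` iterations and is
    non-increasing by the elitism contract of the search.
    """

    selected_features: tuple[int, ...]
    selected_feature_names: tuple[str, ...]
    best_fitness_trajectory: tuple[float, ...]
    final_error_rate: float
    final_accuracy: float
    n_total_features: int
    config_echo: dict[str, Any]
    seed: int

    @property
    def n_selected(self) -> int:
        return len(self.selected_features)

    @property
    def reduction_rate(self) -> float:
        return 1.0 - self.n_selected / self.n_total_features

    def to_dict(self) -> dict[str, Any]:
        return {
            "selected_features": list(self.selected_features),
            "selected_feature_names": list(self.selected_feature_names),
            "n_selected": self.n_selected,
            "n_total_features": self.n_total_features,
            "reduction_rate": self.reduction_rate,
            "final_error_rate": self.final_error_rate,
            "final_accuracy": self.final_accuracy,
            "best_fitness_trajectory": list(self.best_fitness_trajectory),
            "config": self.config_echo,
            "seed": self.seed,
        }


def _coerce_numeric(frame: pd.DataFrame, path: str) -> np.ndarray:
    """Convert a DataFrame to floats, naming the first offending cell."""
    try:
        return frame.to_numpy(dtype=float)
    except (TypeError, ValueError):
        pass
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"{path}: non-numeric expression value {frame[col][row]!r} "
                f"at row {row!r}, column {col!r}"
            )
        if converted.isna().any():
            row = converted.isna().idxmax()
            raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
    raise ValueError(f"{path}: matrix could not be converted to numbers")


def read_dataset(
    path: str | os.PathLike,
    label_column: str | None = None,
    label_file: str | os.PathLike | None = None,
    delimiter: str = ",",
    transpose: bool = False,
) -> LabeledDataset:
    """Read a labelled expression matrix from delimited text.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    label_column
        Name of the column holding class labels (after any transpose).
    label_file
        Alternative to ``label_column``: a sidecar file with one label per
        line, in sample order.
    delimiter
        Field separator, default comma.
    transpose
        If set, rows of the file are features and columns are samples; the
        table is transposed before assembly, so the first column is taken
        as feature names and the header as sample ids.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"dataset file not found: {path}")
    if (label_column is None) == (label_file is None):
        raise ValueError("provide exactly one of label_column or label_file")

    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    if transpose:
        frame = frame.T

    labels: list
    if label_column is not None:
        if label_column not in frame.columns:
            raise ValueError(
                f"{path}: label column {label_column!r} not found "
                f"(columns: {list(frame.columns)[:10]}...)"
            )
        labels = frame[label_column].tolist()
        frame = frame.drop(columns=[label_column])
    else:
        with open(os.fspath(label_file)) as fh:
            labels = [line.strip() for line in fh if line.strip()]

    matrix = _coerce_numeric(frame, path)
    if len(labels) != matrix.shape[0]:
        raise ValueError(
            f"{path}: {len(labels)} labels for {matrix.shape[0]} samples"
        )
    labels = [str(l) if not isinstance(l, numbers.Number) else l for l in labels]
    if len(set(labels)) < 2:
        raise ValueError(f"{path}: fewer than 2 distinct classes in labels")

    return LabeledDataset(
        matrix=matrix,
        labels=tuple(labels),
        feature_names=tuple(str(c) for c in frame.columns),
        sample_ids=tuple(str(i) for i in frame.index),
    )


def write_report(result: SelectionResult, path: str | os.PathLike,
                 format: str = "json") -> None:
    """Write a selection report as JSON (full record) or TSV (feature list)."""
    path = os.fspath(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(result.to_dict(), fh, indent=2)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for idx, name in zip(result.selected_features,
                                 result.selected_feature_names):
                fh.write(f"{idx}\t{name}\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")
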