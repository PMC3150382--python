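"""Labelled square proximity matrices and pairwise distance computations.

Two thin containers around a numpy array plus a label index:

* :class:`DistanceMatrix` — symmetric, zero diagonal, nonnegative;
* :class:`SimilarityMatrix` — symmetric (diagonal unconstrained).

Both read and write square TSV/CSV files with a header row and a first
column of labels.  Pairwise distances between expression-like sample rows
are computed either as Euclidean distance or as the Pearson correlation
distance 1 - r.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError

SYMMETRY_TOL = 1e-8


def _offending_cells(mask: np.ndarray, labels: Sequence[str],
                     limit: int = 5) -> str:
    cells = np.argwhere(mask)[:limit]
    return ", ".join(f"({labels[i]}, {labels[j]})" for i, j in cells)


class _SquareMatrix:
    """Symmetric labelled matrix; validation happens at construction."""

    _kind = "square matrix"

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = tuple(str(x) for x in labels)
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError(
                f"{self._kind} must be square, got shape {values.shape}")
        if len(labels) != values.shape[0]:
            raise ValidationError(
                f"{len(labels)} labels for a {values.shape[0]}x{values.shape[1]} matrix")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate labels: {dupes}")
        nan = np.isnan(values)
        if nan.any():
            raise ValidationError(
                f"{self._kind} contains NaN at cells "
                f"{_offending_cells(nan, labels)}")
        asym = np.abs(values - values.T) > SYMMETRY_TOL
        if asym.any():
            raise ValidationError(
                f"{self._kind} is not symmetric at cells "
                f"{_offending_cells(asym, labels)}")
        self.labels = labels
        # enforce exact symmetry so downstream lookups are order-independent
        self.values = (values + values.T) / 2.0
        self._index = {lab: i for i, lab in enumerate(labels)}
        self._validate()

    def _validate(self) -> None:
        pass

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise ValidationError(f"unknown label {label!r}") from None

    def indexer(self, labels: Iterable[str]) -> np.ndarray:
        return np.fromiter((self.index(x) for x in labels), dtype=np.intp)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def permuted(self, order: Sequence[str]) -> np.ndarray:
        """Matrix values reindexed by ``order`` (must permute the labels)."""
        if sorted(order) != sorted(self.labels):
            raise ValidationError("order is not a permutation of the matrix labels")
        idx = self.indexer(order)
        return self.values[np.ix_(idx, idx)]

    @classmethod
    def from_file(cls, path: str | os.PathLike):
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls([str(x) for x in df.index], df.to_numpy(dtype=float))

    def to_file(self, path: str | os.PathLike) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.DataFrame(self.values, index=list(self.labels),
                          columns=list(self.labels))
        df.to_csv(path, sep=sep)

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}(n={self.n})"


class DistanceMatrix(_SquareMatrix):
    _kind = "distance matrix"

    def _validate(self) -> None:
        diag = np.abs(np.diag(self.values)) > SYMMETRY_TOL
        if diag.any():
            bad = [self.labels[i] for i in np.flatnonzero(diag)[:5]]
            raise ValidationError(f"distance matrix diagonal is nonzero at {bad}")
        np.fill_diagonal(self.values, 0.0)
        if (self.values < 0).any():
            neg = self.values < 0
            raise ValidationError(
                "negative distances at cells "
                f"{_offending_cells(neg, self.labels)}")


class SimilarityMatrix(_SquareMatrix):
    _kind = "similarity matrix"


def _read_data(path: str | os.PathLike) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.map(str)
    return df


def euclidean_distances(data: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between rows (samples) of ``data``."""
    vals = squareform(pdist(data.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(list(data.index), vals)


def pearson_distances(data: pd.DataFrame) -> DistanceMatrix:
    """Pearson correlation distance 1 - r between rows of ``data``.

    Constant rows have undefined correlation and are rejected.
    """
    x = data.to_numpy(dtype=float)
    if np.any(np.std(x, axis=1) == 0):
        bad = [str(data.index[i]) for i in np.flatnonzero(np.std(x, axis=1) == 0)[:5]]
        raise ValidationError(f"constant rows have no Pearson correlation: {bad}")
    r = np.corrcoef(x)
    vals = 1.0 - r
    np.fill_diagonal(vals, 0.0)
    vals[vals < 0] = 0.0  # guard tiny negative rounding of perfectly correlated rows
    return DistanceMatrix(list(data.index), vals)


def similarity_from_data(data: pd.DataFrame) -> SimilarityMatrix:
    """Pearson correlation coefficients between rows, as used in proximity views."""
    return SimilarityMatrix(list(data.index), np.corrcoef(data.to_numpy(dtype=float)))


METRICS = {
    "euclidean": euclidean_distances,
    "pearson": pearson_distances,
}


def compute_distances(data: pd.DataFrame, metric: str) -> DistanceMatrix:
    try:
        fn = METRICS[metric]
    except KeyError:
        raise ValidationError(
            f"unknown metric {metric!r}; choose from {sorted(METRICS)}") from None
    return fn(data)
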