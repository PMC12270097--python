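"""Labeled square distance matrices with TSV round-trip."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

_SYMMETRY_TOL = 1e-12


class DistanceMatrix:
    """Square symmetric nonnegative matrix with zero diagonal and labels.

    Parameters
    ----------
    values : array-like, shape (n, n)
        Pairwise distances. Must be symmetric within 1e-12 and have an
        exactly-zero diagonal; tiny asymmetries are symmetrized.
    labels : sequence of str
        Row/column identifiers, unique.
    """

    def __init__(self, values, labels: Sequence[str]):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"distance matrix must be square, got {values.shape}")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(values, values.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(values < -_SYMMETRY_TOL):
            raise ValueError("distance matrix has negative entries")
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        self.values = values
        self.labels = list(labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        i, j = pair
        return self.values[self.labels.index(i), self.labels.index(j)]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DistanceMatrix)
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Restrict to the given labels, in the given order."""
        idx = [self.labels.index(str(x)) for x in labels]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], [self.labels[i] for i in idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={len(self)})"
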