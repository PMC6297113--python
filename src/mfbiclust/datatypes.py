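"""Core containers: labeled data matrices and bicluster index sets.

A :class:`DataMatrix` is the object every pipeline stage consumes and
produces: an ``m x n`` array of samples (rows) by variables (columns) with
unique string labels on both axes.  Variables are typically NMR chemical
shifts (ppm) or MS mass-to-charge ratios.  A :class:`Bicluster` is a pair of
index sets into such a matrix, and a :class:`BiclusterSet` an ordered
collection of them (overlap between members is allowed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "Bicluster",
    "BiclusterSet",
    "read_matrix",
    "write_matrix",
]


@dataclass
class DataMatrix:
    """Labeled 2-D array of samples (rows) by variables (columns).

    Parameters
    ----------
    values
        Real ``m x n`` array; all entries must be finite.
    row_labels
        Unique sample identifiers, length ``m``.
    col_labels
        Unique variable identifiers (e.g. ppm or m/z values as strings),
        length ``n``.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        m, n = self.values.shape
        self.row_labels = [str(x) for x in self.row_labels]
        self.col_labels = [str(x) for x in self.col_labels]
        if len(self.row_labels) != m:
            raise ValueError(f"expected {m} row labels, got {len(self.row_labels)}")
        if len(self.col_labels) != n:
            raise ValueError(f"expected {n} col labels, got {len(self.col_labels)}")
        if len(set(self.row_labels)) != m:
            raise ValueError("row labels must be unique")
        if len(set(self.col_labels)) != n:
            raise ValueError("col labels must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        row_prefix: str = "S",
        col_prefix: str = "V",
    ) -> "DataMatrix":
        """Wrap a bare array with generated ``S1..Sm`` / ``V1..Vn`` labels."""
        values = np.asarray(values, dtype=float)
        m, n = values.shape
        return cls(
            values,
            [f"{row_prefix}{i + 1}" for i in range(m)],
            [f"{col_prefix}{j + 1}" for j in range(n)],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def with_values(self, values: np.ndarray) -> "DataMatrix":
        """Copy carrying the same labels but new values (same shape)."""
        if np.shape(values) != self.shape:
            raise ValueError("replacement values must keep the matrix shape")
        return DataMatrix(np.asarray(values, float), list(self.row_labels), list(self.col_labels))


def read_matrix(path: str | Path, sep: str | None = None) -> DataMatrix:
    """Read a labeled matrix from delimited text.

    The first column holds sample labels, the header row variable labels.
    The separator is inferred from the suffix (``.csv`` -> comma, otherwise
    tab) unless given explicitly.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return DataMatrix.from_dataframe(df)


def write_matrix(matrix: DataMatrix, path: str | Path, sep: str | None = None) -> Path:
    """Write a labeled matrix as delimited text (inverse of :func:`read_matrix`)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.to_dataframe().to_csv(path, sep=sep)
    return path


@dataclass(frozen=True)
class Bicluster:
    """A submatrix given by a set of row indices and a set of column indices."""

    rows: frozenset[int]
    cols: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", frozenset(int(i) for i in self.rows))
        object.__setattr__(self, "cols", frozenset(int(j) for j in self.cols))
        if not self.rows or not self.cols:
            raise ValueError("a bicluster needs non-empty row and column sets")
        if any(i < 0 for i in self.rows) or any(j < 0 for j in self.cols):
            raise ValueError("bicluster indices must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.rows), len(self.cols)

    def to_dict(self) -> dict:
        return {"rows": sorted(self.rows), "cols": sorted(self.cols)}


@dataclass
class BiclusterSet:
    """Ordered collection of biclusters; members may overlap."""

    biclusters: list[Bicluster] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.biclusters)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, i: int) -> Bicluster:
        return self.biclusters[i]

    def row_sets(self) -> list[set[int]]:
        return [set(b.rows) for b in self.biclusters]

    def col_sets(self) -> list[set[int]]:
        return [set(b.cols) for b in self.biclusters]

    def to_dict(self) -> dict:
        return {"biclusters": [b.to_dict() for b in self.biclusters]}

    @classmethod
    def from_dict(cls, d: dict) -> "BiclusterSet":
        return cls([Bicluster(frozenset(b["rows"]), frozenset(b["cols"])) for b in d["biclusters"]])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BiclusterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_index_lists(
        cls,
        pairs: Iterable[tuple[Sequence[int], Sequence[int]]],
    ) -> "BiclusterSet":
        return cls([Bicluster(frozenset(r), frozenset(c)) for r, c in pairs])
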