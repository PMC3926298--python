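"""Contingency tables built from the NN digraph.

Two table types drive the symmetry tests:

* the nearest-neighbor contingency table (NNCT), a k x k table whose
  (i, j) cell counts points of base class i whose NN is of class j — its
  row sums are the class sizes;
* the Q-symmetry table, a k x (m_max+1) table whose (i, m) cell counts
  class-i points serving as NN to exactly m other points (in-degree m).

The Q-symmetry table is routinely reduced by merging the sparse high-m
columns; the default reduction merges all columns m >= 2 into one, giving
a k x 3 table.  An adaptive alternative merges the highest column into its
left neighbor until Conover's expected-count criterion holds (no expected
cell below 1, at most 20% of cells below 5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nn_core import NNDigraph, PointPattern

__all__ = [
    "NNCT",
    "QSymmetryTable",
    "build_nnct",
    "build_qsym",
    "reduce_qsym",
    "read_nnct_csv",
    "read_qsym_csv",
]


def _check_classes(pattern: PointPattern) -> None:
    sizes = pattern.class_sizes
    if pattern.k < 2:
        raise ValueError("at least 2 classes are required")
    if np.any(sizes == 0):
        raise ValueError("every class must contain at least one point")


@dataclass
class NNCT:
    """k x k base-class by NN-class count table."""

    counts: np.ndarray
    classes: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("NNCT counts must be k x k")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def class_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="class")

    def to_json(self) -> str:
        return json.dumps({
            "type": "NNCT", "classes": [str(c) for c in self.classes],
            "counts": self.counts.tolist(), "provenance": self.provenance,
        })

    @classmethod
    def from_json(cls, s: str) -> "NNCT":
        d = json.loads(s)
        return cls(np.array(d["counts"]), d["classes"], d.get("provenance", {}))


@dataclass
class QSymmetryTable:
    """k x (m_max+1) table of 'times served as NN' counts per class.

    ``reduced`` marks a table whose trailing columns were merged;
    ``merge_boundary`` is the first merged column (2 under the default
    reduction, so the last column counts in-degrees >= 2).
    """

    counts: np.ndarray
    classes: list
    reduced: bool = False
    merge_boundary: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.classes):
            raise ValueError("counts rows must match classes")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]

    @property
    def class_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def column_labels(self) -> list:
        c = self.counts.shape[1]
        if self.reduced and self.merge_boundary is not None:
            labs = [str(m) for m in range(self.merge_boundary)]
            labs.append(f">={self.merge_boundary}")
            return labs
        return [str(m) for m in range(c)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes,
                            columns=self.column_labels())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="class")

    def to_json(self) -> str:
        return json.dumps({
            "type": "QSymmetryTable", "classes": [str(c) for c in self.classes],
            "counts": self.counts.tolist(), "reduced": self.reduced,
            "merge_boundary": self.merge_boundary, "provenance": self.provenance,
        })

    @classmethod
    def from_json(cls, s: str) -> "QSymmetryTable":
        d = json.loads(s)
        return cls(np.array(d["counts"]), d["classes"], d["reduced"],
                   d.get("merge_boundary"), d.get("provenance", {}))


def build_nnct(pattern: PointPattern, g: NNDigraph) -> NNCT:
    """Cross-tabulate base-point class against NN class."""
    _check_classes(pattern)
    if g.n != pattern.n:
        raise ValueError("pattern and digraph sizes differ")
    codes = pattern.label_codes
    k = pattern.k
    flat = codes * k + codes[g.nn_index]
    counts = np.bincount(flat, minlength=k * k).reshape(k, k)
    return NNCT(counts, pattern.classes)


def build_qsym(pattern: PointPattern, g: NNDigraph, m_max: int = 5) -> QSymmetryTable:
    """Tabulate per class the number of times each point serves as NN.

    In-degrees above ``m_max`` are pooled into the last column (for planar
    Euclidean data the default ``m_max=5`` pools the geometrically rare
    in-degree 6 with 5).
    """
    _check_classes(pattern)
    codes = pattern.label_codes
    indeg = np.minimum(g.in_degrees, m_max)
    k = pattern.k
    flat = codes * (m_max + 1) + indeg
    counts = np.bincount(flat, minlength=k * (m_max + 1)).reshape(k, m_max + 1)
    return QSymmetryTable(counts, pattern.classes, reduced=False)


def _conover_ok(counts: np.ndarray) -> bool:
    # expected counts under row/column independence
    counts = counts.astype(float)
    n = counts.sum()
    e = np.outer(counts.sum(1), counts.sum(0)) / n
    return bool(np.all(e >= 1) and (e < 5).mean() <= 0.20)


def reduce_qsym(t: QSymmetryTable, rule: str = "paper-default") -> QSymmetryTable:
    """Merge sparse high-m columns of a full Q-symmetry table.

    ``paper-default`` merges all columns m >= 2 into one (k x 3 result);
    ``expected-count`` merges the last column into its left neighbor until
    Conover's criterion holds or only 2 columns remain.
    """
    if t.reduced:
        raise ValueError("table is already reduced")
    c = t.counts
    if rule == "paper-default":
        if c.shape[1] <= 3:
            merged = c.copy()
            boundary = c.shape[1] - 1
        else:
            merged = np.column_stack([c[:, :2], c[:, 2:].sum(axis=1)])
            boundary = 2
        return QSymmetryTable(merged, t.classes, reduced=True,
                              merge_boundary=boundary, provenance=dict(t.provenance))
    if rule == "expected-count":
        merged = c.astype(int).copy()
        while merged.shape[1] > 2 and not _conover_ok(merged):
            merged = np.column_stack(
                [merged[:, :-2], merged[:, -2] + merged[:, -1]])
        return QSymmetryTable(merged, t.classes, reduced=True,
                              merge_boundary=merged.shape[1] - 1,
                              provenance=dict(t.provenance))
    raise ValueError(f"unknown reduction rule {rule!r}")


def read_nnct_csv(path, sep=None) -> NNCT:
    """Read a k x k NNCT from delimited text; header = class names, first
    column = class names."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return NNCT(df.to_numpy(int), list(df.index))


def read_qsym_csv(path, sep=None) -> QSymmetryTable:
    """Read a Q-symmetry table from delimited text.

    Column headers are the serving-count categories; a last header of the
    form ``>=m`` marks a reduced table with merge boundary ``m``.
    """
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    cols = [str(c) for c in df.columns]
    reduced = any(c.startswith(">=") for c in cols)
    boundary = None
    if reduced:
        boundary = int(cols[-1].lstrip(">="))
    return QSymmetryTable(df.to_numpy(int), list(df.index), reduced=reduced,
                          merge_boundary=boundary)
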