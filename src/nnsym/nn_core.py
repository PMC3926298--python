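"""Nearest-neighbor digraph of a labeled point pattern.

Every point is assigned exactly one nearest neighbor (NN), by Euclidean
distance between planar coordinates or by a user-supplied dissimilarity
matrix.  The resulting digraph (one out-arc per point) carries the
combinatorial summaries that the symmetry tests condition on:

* ``Q_j`` — number of points serving as NN to exactly ``j`` other points
  (the in-degree distribution of the digraph);
* ``Q``   — number of ordered pairs of distinct points that share a NN,
  ``Q = 2(Q_2 + 3Q_3 + 6Q_4 + 10Q_5 + 15Q_6)``;
* ``Q~``  — the general-dimension form ``2 * sum_j C(j,2) Q_j``, identical
  to ``Q`` whenever no point serves as NN more than six times (always the
  case for planar Euclidean data);
* ``R``   — twice the number of reflexive pairs (pairs of points that are
  each other's NN).

No edge correction of any kind is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("nnsym")

__all__ = [
    "PointPattern",
    "NNDigraph",
    "nearest_neighbors",
    "graph_summaries",
]


@dataclass
class PointPattern:
    """A labeled planar point set, or a labeled dissimilarity matrix.

    Parameters
    ----------
    coords
        ``(n, 2)`` array of planar coordinates (arbitrary units), or None
        when ``dissim`` is given.
    labels
        Length-``n`` sequence of class identifiers.  Class order is
        first-appearance order in the input unless ``class_order`` is set.
    dissim
        Optional ``(n, n)`` symmetric dissimilarity matrix with minimal
        diagonal; replaces Euclidean distances when given.
    window
        Optional axis-aligned rectangle ``(xmin, xmax, ymin, ymax)``;
        informational only (no edge correction is performed).
    """

    coords: Optional[np.ndarray] = None
    labels: Sequence = ()
    dissim: Optional[np.ndarray] = None
    window: Optional[tuple] = None
    class_order: Optional[Sequence] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.coords is None and self.dissim is None:
            raise ValueError("either coords or dissim must be given")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.ndim != 2 or self.coords.shape[1] != 2:
                raise ValueError("coords must be an (n, 2) array")
            if not np.all(np.isfinite(self.coords)):
                raise ValueError("non-finite coordinates")
            n = self.coords.shape[0]
        if self.dissim is not None:
            self.dissim = np.asarray(self.dissim, dtype=float)
            d = self.dissim
            if d.ndim != 2 or d.shape[0] != d.shape[1]:
                raise ValueError("dissim must be a square matrix")
            off = ~np.eye(d.shape[0], dtype=bool)
            if not np.all(np.isfinite(d[off])):
                raise ValueError("non-finite off-diagonal dissimilarities")
            if not np.allclose(d, d.T):
                raise ValueError("dissimilarity matrix must be symmetric")
            if np.any(d.diagonal()[:, None] > d + 1e-12 * np.abs(d)):
                raise ValueError(
                    "diagonal of dissimilarity matrix must be minimal in its row"
                )
            n = d.shape[0]
        if len(self.labels) != n:
            raise ValueError("labels length does not match number of points")
        if n < 2:
            raise ValueError("degenerate pattern: need at least 2 points")
        if self.class_order is None:
            # first-appearance order
            _, idx = np.unique(self.labels, return_index=True)
            self.class_order = list(self.labels[np.sort(idx)])
        else:
            self.class_order = list(self.class_order)
            if set(self.class_order) != set(np.unique(self.labels).tolist()):
                raise ValueError("class_order does not match observed labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> list:
        return list(self.class_order)

    @property
    def k(self) -> int:
        return len(self.class_order)

    @property
    def label_codes(self) -> np.ndarray:
        """Integer codes of the labels in class order (cached)."""
        if getattr(self, "_codes", None) is None:
            lut = {c: i for i, c in enumerate(self.class_order)}
            self._codes = np.fromiter((lut[v] for v in self.labels),
                                      dtype=np.intp, count=self.n)
        return self._codes

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.label_codes, minlength=self.k)

    def distance_matrix(self) -> np.ndarray:
        if self.dissim is not None:
            return self.dissim.copy()
        return cdist(self.coords, self.coords)

    def subset(self, keep_classes: Sequence) -> "PointPattern":
        """Restrict the pattern to the given classes (restricted post hoc)."""
        keep = set(keep_classes)
        mask = np.fromiter((v in keep for v in self.labels), dtype=bool,
                           count=self.n)
        order = [c for c in self.class_order if c in keep]
        return PointPattern(
            coords=None if self.coords is None else self.coords[mask],
            labels=self.labels[mask],
            dissim=None if self.dissim is None else self.dissim[np.ix_(mask, mask)],
            window=self.window,
            class_order=order,
        )

    def relabel(self, labels: Sequence, class_order=None) -> "PointPattern":
        """Same geometry, new labels (pooling / randomization)."""
        return PointPattern(
            coords=self.coords, labels=labels, dissim=self.dissim,
            window=self.window, class_order=class_order,
        )

    @classmethod
    def from_csv(cls, path, sep=None, **kw) -> "PointPattern":
        """Read a delimited text file with header columns x, y, label."""
        import pandas as pd

        df = pd.read_csv(path, sep=sep, engine="python")
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no data rows")
        cols = {c.lower(): c for c in df.columns}
        for req in ("x", "y", "label"):
            if req not in cols:
                raise ValueError(f"{path}: missing required column '{req}'")
        return cls(
            coords=df[[cols["x"], cols["y"]]].to_numpy(float),
            labels=df[cols["label"]].astype(str).to_numpy(),
            **kw,
        )

    @classmethod
    def from_dissim_csv(cls, dissim_path, labels_path, sep=None) -> "PointPattern":
        """Read a square dissimilarity matrix plus a one-column label file."""
        import pandas as pd

        d = pd.read_csv(dissim_path, sep=sep, engine="python", header=None)
        lab = pd.read_csv(labels_path, sep=sep, engine="python", header=None)
        return cls(dissim=d.to_numpy(float), labels=lab.iloc[:, 0].astype(str).to_numpy())


@dataclass
class NNDigraph:
    """The NN assignment of a pattern plus its combinatorial summaries."""

    nn_index: np.ndarray        # point -> index of its NN
    nn_dist: np.ndarray
    tie_flags: np.ndarray       # True where the NN was tie-broken
    in_degrees: np.ndarray = field(init=False)
    Q_j: np.ndarray = field(init=False)   # Q_j[j] = #points with in-degree j
    Q: int = field(init=False)
    Q_general: int = field(init=False)
    R: int = field(init=False)

    def __post_init__(self):
        n = len(self.nn_index)
        self.in_degrees = np.bincount(self.nn_index, minlength=n)
        self.Q_j = np.bincount(self.in_degrees)
        j = np.arange(len(self.Q_j))
        # Q caps the planar formula at j = 6; Q~ sums over all observed j.
        jq = j[j <= 6]
        self.Q = int((jq * (jq - 1) * self.Q_j[: len(jq)]).sum())
        self.Q_general = int((j * (j - 1) * self.Q_j).sum())
        self.R = int((self.nn_index[self.nn_index] == np.arange(n)).sum())

    @property
    def n(self) -> int:
        return len(self.nn_index)


def nearest_neighbors(pattern: PointPattern, tie_rule: str = "lowest-index",
                      seed=None) -> NNDigraph:
    """Assign each point its nearest neighbor.

    Ties in NN distance are resolved to the lowest point index by default
    (deterministic and reproducible); ``tie_rule="random"`` breaks them
    uniformly at random using ``seed``.  Tie-broken points are flagged.
    """
    d = pattern.distance_matrix()
    n = d.shape[0]
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    nn_dist = d[np.arange(n), nn]
    ties = (d == nn_dist[:, None]).sum(axis=1) > 1
    if tie_rule == "random" and ties.any():
        rng = np.random.default_rng(seed)
        for i in np.flatnonzero(ties):
            cand = np.flatnonzero(d[i] == nn_dist[i])
            nn[i] = rng.choice(cand)
    elif tie_rule not in ("lowest-index", "random"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    if np.any(nn_dist == 0):
        logger.warning("duplicate (zero-distance) points present; "
                       "a point's NN is at distance 0")
    return NNDigraph(nn_index=nn, nn_dist=nn_dist, tie_flags=ties)


def graph_summaries(g: NNDigraph) -> dict:
    """Summaries of the NN digraph: Q_j vector, Q, Q~, and R."""
    return {"Q_j": g.Q_j.copy(), "Q": g.Q, "Q_general": g.Q_general, "R": g.R}
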