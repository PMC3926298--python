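"""Dixon's symmetry test under random labeling (RL).

Conditional on the observed NN digraph, randomly permuting the class
labels induces an exact distribution for every NNCT cell N_ij.  The first
two moments have closed forms in the class sizes n_i, the shared-NN count
Q and the reflexivity count R of the digraph, with E[N_ij] = n p_ij and

    Var[N_ij]      = n p_ij + Q p_iij + (n^2 - 3n - Q + R) p_iijj
                     - (n p_ij)^2,
    Cov[N_12,N_21] = R p_12 + (n - R)(p_112 + p_122)
                     + (n^2 - 3n - Q + R) p_1122 - n^2 p_12 p_21,

where p with subscripts is the falling-factorial probability that an
ordered tuple of distinct points carries the indicated classes.  The
general cell covariance Cov[N_ij, N_kl] is obtained here by the same
arc-pair decomposition that produces the displayed formulas: N_ij is a sum
of indicators over the n out-arcs, and an ordered pair of arcs falls into
one of six coincidence classes whose counts are

    same arc: n;   reflexive pair: R;   shared target: Q;
    head-to-tail chains: n - R each;    all four points distinct:
    n^2 - 3n - Q + R.

Weighting each class by its tuple probability gives the exact second
moment, which specializes to the displayed variance and covariance and is
validated against exhaustive enumeration of labelings (the oracle below).

Two-class test: Z_D = (N_12 - N_21) / sqrt(Var[N_12 - N_21]), asymptotic
N(0,1).  Multiclass: the vector T_S of off-diagonal differences N_ij - N_ji
(i < j, lexicographic) with covariance matrix Sigma_sym yields the
quadratic form X^2_D = T_S' Sigma_sym^- T_S, chi-square with df =
rank(Sigma_sym) (k(k-1)/2 when non-degenerate).  Under CSR the observed
Q and R are plugged in; the test is then conditional on them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, factorial

import numpy as np
from scipy import linalg, stats

from .nn_core import NNDigraph, PointPattern, nearest_neighbors
from .pielou import TestResult
from .tables import NNCT, build_nnct

__all__ = [
    "RLMoments",
    "SymmetryVector",
    "rl_moments",
    "nnct_cell_covariance",
    "ts_covariance",
    "symmetry_vector",
    "dixon_z",
    "dixon_z_pairwise",
    "dixon_overall",
    "rl_enumeration_oracle",
]


@dataclass
class RLMoments:
    """Exact random-labeling moments of NNCT cells on a fixed digraph.

    Holds the class sizes and the digraph summaries (n, Q, R) and exposes
    tuple probabilities, expected counts, and cell (co)variances.
    """

    class_sizes: np.ndarray
    Q: int
    R: int

    def __post_init__(self):
        self.class_sizes = np.asarray(self.class_sizes, dtype=int)
        if np.any(self.class_sizes < 1):
            raise ValueError("all class sizes must be >= 1")
        self.n = int(self.class_sizes.sum())
        if self.n < 4:
            raise ValueError("too few points for RL moments (need n >= 4)")

    @property
    def k(self) -> int:
        return len(self.class_sizes)

    def tuple_probability(self, classes) -> float:
        """Probability that an ordered tuple of distinct points has the
        given classes, e.g. (i, i, j) -> p_iij."""
        classes = list(classes)
        num = 1.0
        used = {}
        for c in classes:
            a = used.get(c, 0)
            num *= self.class_sizes[c] - a
            used[c] = a + 1
        den = 1.0
        for t in range(len(classes)):
            den *= self.n - t
        return num / den

    def expected(self, i: int, j: int) -> float:
        """E[N_ij] = n * p_ij (exact; ~ n_i n_j / n for large n)."""
        return self.n * self.tuple_probability((i, j))

    def var(self, i: int, j: int) -> float:
        return nnct_cell_covariance(self, i, j, i, j)

    def cov(self, i: int, j: int, k: int, l: int) -> float:
        return nnct_cell_covariance(self, i, j, k, l)


def rl_moments(class_sizes, Q: int, R: int) -> RLMoments:
    """Construct :class:`RLMoments` from class sizes and observed Q, R."""
    return RLMoments(np.asarray(class_sizes), int(Q), int(R))


def moments_from_pattern(pattern: PointPattern, g: NNDigraph | None = None
                         ) -> RLMoments:
    if g is None:
        g = nearest_neighbors(pattern)
    return RLMoments(pattern.class_sizes, g.Q, g.R)


def nnct_cell_covariance(m: RLMoments, i: int, j: int, k: int, l: int) -> float:
    """Exact Cov[N_ij, N_kl] under RL, i != j and k != l.

    Computed from the arc-pair decomposition: each coincidence class of
    ordered arc pairs contributes its count times the tuple probability of
    the distinct points involved, subject to the label-compatibility
    deltas.  Specializes to the closed-form variance (i,j,i,j) and the
    reflexive covariance (i,j,j,i).
    """
    for c in (i, j, k, l):
        if not (0 <= c < m.k):
            raise ValueError(f"class index {c} out of range")
    if i == j or k == l:
        raise ValueError("cell covariance defined for off-diagonal cells")
    n, Q, R = m.n, m.Q, m.R
    tp = m.tuple_probability
    s = 0.0
    if i == k and j == l:                      # same arc
        s += n * tp((i, j))
    if i == l and j == k:                      # reflexive arc pair
        s += R * tp((i, j))
    if j == l:                                 # distinct arcs, shared target
        s += Q * tp((i, k, j))
    if j == k:                                 # chain: target of 1st = base of 2nd
        s += (n - R) * tp((i, j, l))
    if i == l:                                 # chain: target of 2nd = base of 1st
        s += (n - R) * tp((k, i, j))
    s += (n * n - 3 * n - Q + R) * tp((i, j, k, l))
    return s - n * n * tp((i, j)) * tp((k, l))


def ts_covariance(m: RLMoments, i: int, j: int, k: int, l: int) -> float:
    """Cov[N_ij - N_ji, N_kl - N_lk]; exactly zero when all four classes
    are distinct (the four raw covariances coincide and cancel)."""
    if len({i, j, k, l}) == 4:
        return 0.0
    return (nnct_cell_covariance(m, i, j, k, l)
            - nnct_cell_covariance(m, i, j, l, k)
            - nnct_cell_covariance(m, j, i, k, l)
            + nnct_cell_covariance(m, j, i, l, k))


@dataclass
class SymmetryVector:
    """T_S = (N_ij - N_ji) for i < j in lexicographic order, with its RL
    covariance matrix."""

    t_s: np.ndarray
    sigma: np.ndarray
    pairs: list
    rank: int = field(init=False)
    tol: float = 1e-10

    def __post_init__(self):
        ev = np.linalg.eigvalsh(self.sigma)
        scale = max(ev.max(), 0.0)
        if np.any(ev < -self.tol * max(scale, 1.0)):
            raise ValueError("Sigma_sym has a significantly negative eigenvalue")
        self.rank = int((ev > self.tol * max(scale, 1.0)).sum())


def symmetry_vector(t: NNCT, m: RLMoments) -> SymmetryVector:
    pairs = [(i, j) for i in range(t.k) for j in range(i + 1, t.k)]
    ts = np.array([float(t.counts[i, j] - t.counts[j, i]) for i, j in pairs])
    ks = len(pairs)
    sigma = np.empty((ks, ks))
    for a, (i, j) in enumerate(pairs):
        for b in range(a, ks):
            k, l = pairs[b]
            sigma[a, b] = sigma[b, a] = ts_covariance(m, i, j, k, l)
    return SymmetryVector(t_s=ts, sigma=sigma, pairs=pairs)


def _pair_var(m: RLMoments, i: int, j: int) -> float:
    return (nnct_cell_covariance(m, i, j, i, j)
            + nnct_cell_covariance(m, j, i, j, i)
            - 2 * nnct_cell_covariance(m, i, j, j, i))


def dixon_z(t: NNCT, m: RLMoments | None = None) -> TestResult:
    """Two-class Dixon symmetry test Z_D, asymptotically N(0,1)."""
    if t.k != 2:
        raise ValueError("dixon_z requires exactly 2 classes; "
                         "use dixon_z_pairwise or dixon_overall for k > 2")
    if m is None:
        raise ValueError("RL moments (class sizes, Q, R) are required")
    return dixon_z_pairwise(t, m, 0, 1)


def dixon_z_pairwise(t: NNCT, m: RLMoments, i: int, j: int) -> TestResult:
    """Pairwise Z_D^{ij} = (N_ij - N_ji)/sqrt(Var[N_ij - N_ji]) with the
    variance computed from the full pattern's n, Q, R (unrestricted)."""
    if i == j:
        raise ValueError("need two distinct classes")
    var = _pair_var(m, i, j)
    diff = float(t.counts[i, j] - t.counts[j, i])
    if var <= 0:
        raise ValueError(
            f"degenerate configuration: Var[N_ij - N_ji] = {var:.3g} <= 0 "
            f"(n={m.n}, Q={m.Q}, R={m.R}, sizes={m.class_sizes.tolist()})")
    z = diff / np.sqrt(var)
    p_two = 2 * float(stats.norm.sf(abs(z)))
    return TestResult(
        statistic=float(z), df=None, p_value=min(1.0, p_two),
        method="Dixon symmetry Z_D", sidedness="two-sided",
        extras={
            "pair": (t.classes[i], t.classes[j]),
            "N_ij": int(t.counts[i, j]), "N_ji": int(t.counts[j, i]),
            "variance": var, "Q": m.Q, "R": m.R,
            "p_greater": float(stats.norm.sf(z)),
            "p_less": float(stats.norm.cdf(z)),
        },
    )


def dixon_overall(t: NNCT, m: RLMoments) -> TestResult:
    """Overall symmetry test X^2_D = T_S' Sigma_sym^- T_S.

    The generalized inverse is Moore-Penrose with relative eigenvalue
    tolerance 1e-10; df is the numerical rank of Sigma_sym.
    """
    sv = symmetry_vector(t, m)
    if sv.rank == 0:
        raise ValueError("Sigma_sym is numerically zero")
    sigma_inv = linalg.pinvh(sv.sigma, rtol=sv.tol)
    stat = float(sv.t_s @ sigma_inv @ sv.t_s)
    df = sv.rank
    p = float(stats.chi2.sf(stat, df))
    return TestResult(
        statistic=stat, df=df, p_value=p,
        method="Dixon overall symmetry X^2_D",
        extras={"T_S": sv.t_s, "Sigma_sym": sv.sigma,
                "pairs": [(t.classes[i], t.classes[j]) for i, j in sv.pairs],
                "rank": sv.rank},
    )


def rl_enumeration_oracle(g: NNDigraph, class_sizes, cap: int = 10 ** 6) -> dict:
    """Exact RL moments by exhaustive enumeration of all labelings.

    Enumerates every assignment of labels with the given class sizes over
    the fixed digraph and accumulates exact integer sums, returning
    ``E[N_ij]``, ``Var[N_ij]`` and ``Cov[N_ij, N_kl]`` arrays as exact
    Fractions converted to float.  Intended as an independent oracle for
    the analytic moments on small patterns.
    """
    sizes = np.asarray(class_sizes, dtype=int)
    n = g.n
    if sizes.sum() != n:
        raise ValueError("class sizes must sum to the number of points")
    k = len(sizes)
    total = factorial(n)
    for s in sizes:
        total //= factorial(int(s))
    if total > cap:
        raise ValueError(
            f"{total} labelings exceed the enumeration cap {cap}; "
            "use the analytic RL moments instead")

    cells = [(i, j) for i in range(k) for j in range(k)]
    ncell = len(cells)
    sum1 = np.zeros(ncell, dtype=object)
    sum2 = np.zeros((ncell, ncell), dtype=object)
    nn = g.nn_index

    def assignments(remaining, sizes_left):
        if len(sizes_left) == 1:
            yield (tuple(remaining),)
            return
        for chosen in itertools.combinations(remaining, sizes_left[0]):
            rest = [p for p in remaining if p not in set(chosen)]
            for tail in assignments(rest, sizes_left[1:]):
                yield (chosen,) + tail

    count = 0
    for groups in assignments(list(range(n)), list(sizes)):
        labels = np.empty(n, dtype=np.intp)
        for c, pts in enumerate(groups):
            labels[list(pts)] = c
        flat = labels * k + labels[nn]
        N = np.bincount(flat, minlength=k * k)
        sum1 += N
        sum2 += np.outer(N, N)
        count += 1
    assert count == total

    e = np.empty((k, k), dtype=float)
    var = np.empty((k, k), dtype=float)
    cov = np.empty((k, k, k, k), dtype=float)
    for a, (i, j) in enumerate(cells):
        e[i, j] = float(Fraction(int(sum1[a]), total))
        for b, (kk, ll) in enumerate(cells):
            c = (Fraction(int(sum2[a, b]), total)
                 - Fraction(int(sum1[a]), total) * Fraction(int(sum1[b]), total))
            cov[i, j, kk, ll] = float(c)
        var[i, j] = cov[i, j, i, j]
    return {"E": e, "Var": var, "Cov": cov, "n_labelings": total}
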