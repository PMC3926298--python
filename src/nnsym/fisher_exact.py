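"""Exact conditional inference on the (reduced) Q-symmetry table.

Conditioning on both margins, the probability of a table C_T is the
multiple hypergeometric

    f(C_T) = prod_i [ r_i! / prod_j N_ij! ] / [ n! / prod_j c_j! ],

computed in log space.  Enumerating all tables with the observed margins
yields the two-sided p-value variants:

* table-inclusive   p_inc   = sum of f over {f(C_T) <= p_t};
* table-exclusive   p_exc   = p_inc - p_t;
* mid-p             p_mid   = p_exc + p_t / 2;
* twice-table-inclusive p_t_inc = p_inc + p_t (capped at 1);
* Tocher-randomized p_toc: when p_exc < alpha < p_inc a uniform draw U
  decides between p_inc (U >= (alpha - p_exc)/p_t) and p_exc; outside
  that window p_inc is used.

For tables with more than two rows full enumeration can explode; a Monte
Carlo mode samples from the fixed-margin null by random pairing of row
and column labels and estimates the same p-values with standard errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .tables import QSymmetryTable

__all__ = [
    "ExactResult",
    "table_probability",
    "enumerate_tables",
    "exact_symmetry_pvalues",
    "exact_symmetry_montecarlo",
]

_REL_TOL = 1e-12      # tie tolerance when comparing table probabilities


@dataclass
class ExactResult:
    """The five two-sided exact p-values for one table."""

    p_t: float
    p_inc: float
    p_exc: float
    p_mid: float
    p_t_inc: float
    p_toc: float
    alpha: float
    tocher_u: Optional[float] = None
    seed: Optional[int] = None
    n_tables_enumerated: int = 0
    monte_carlo: bool = False
    standard_errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "p_t", "p_inc", "p_exc", "p_mid", "p_t_inc", "p_toc", "alpha",
            "tocher_u", "seed", "n_tables_enumerated", "monte_carlo",
            "standard_errors")}


def _log_table_probability(counts: np.ndarray) -> float:
    counts = np.asarray(counts)
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    n = counts.sum()
    return float(gammaln(r + 1).sum() + gammaln(c + 1).sum()
                 - gammaln(n + 1) - gammaln(counts + 1).sum())


def table_probability(counts) -> float:
    """Multiple hypergeometric probability of a table given its margins."""
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("negative entries")
    return float(np.exp(_log_table_probability(counts)))


def enumerate_tables(row_sums, col_sums, cap: int = 10 ** 7):
    """Yield all nonnegative integer tables with the given margins.

    Depth-first composition generation row by row with margin pruning.
    """
    row_sums = [int(x) for x in row_sums]
    col_sums = np.asarray(col_sums, dtype=int)
    nrow = len(row_sums)
    count = 0

    def compositions(total, bounds):
        # all vectors 0 <= v_j <= bounds[j] with sum v = total
        if len(bounds) == 1:
            if 0 <= total <= bounds[0]:
                yield (total,)
            return
        lo = max(0, total - int(bounds[1:].sum()))
        hi = min(int(bounds[0]), total)
        for v in range(lo, hi + 1):
            for rest in compositions(total - v, bounds[1:]):
                yield (v,) + rest

    def rows(idx, remaining_cols, acc):
        nonlocal count
        if idx == nrow - 1:
            count += 1
            if count > cap:
                raise ValueError(f"enumeration cap {cap} exceeded; "
                                 "use exact_symmetry_montecarlo")
            yield acc + [tuple(remaining_cols)]
            return
        for comp in compositions(row_sums[idx], remaining_cols):
            yield from rows(idx + 1, remaining_cols - np.array(comp), acc + [comp])

    for tab in rows(0, col_sums.copy(), []):
        yield np.array(tab, dtype=int)


def _count_tables(row_sums, col_sums) -> int:
    """Independent recursive count of fixed-margin tables (no generation)."""
    row_sums = [int(x) for x in row_sums]
    col_sums = tuple(int(x) for x in col_sums)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(idx, cols):
        if idx == len(row_sums) - 1:
            return 1
        total = 0
        for comp in _bounded_compositions(row_sums[idx], cols):
            total += rec(idx + 1, tuple(c - v for c, v in zip(cols, comp)))
        return total

    def _bounded_compositions(total, bounds):
        if len(bounds) == 1:
            if 0 <= total <= bounds[0]:
                yield (total,)
            return
        lo = max(0, total - sum(bounds[1:]))
        hi = min(bounds[0], total)
        for v in range(lo, hi + 1):
            for rest in _bounded_compositions(total - v, bounds[1:]):
                yield (v,) + rest

    return rec(0, col_sums)


def _variants(p_t, p_inc, alpha, rng) -> dict:
    p_exc = max(0.0, p_inc - p_t)
    p_mid = p_exc + p_t / 2.0
    p_t_inc = min(1.0, p_inc + p_t)
    u = None
    if p_exc < alpha < p_inc and p_t > 0:
        u = float(rng.uniform())
        p_toc = p_inc if u >= (alpha - p_exc) / p_t else p_exc
    else:
        p_toc = p_inc
    return {"p_exc": p_exc, "p_mid": p_mid, "p_t_inc": p_t_inc,
            "p_toc": p_toc, "tocher_u": u}


def _counts_of(t) -> np.ndarray:
    if isinstance(t, QSymmetryTable):
        return t.counts
    return np.asarray(t, dtype=int)


def _log_probs_2xc(row_sums, col_sums) -> np.ndarray:
    """Log-probabilities of every 2 x c table with the given margins,
    fully vectorized over the first row (c - 1 free entries)."""
    r1 = int(row_sums[0])
    c = np.asarray(col_sums, dtype=int)
    ncol = len(c)
    n = int(c.sum())
    lgam = gammaln(np.arange(n + 2))
    const = lgam[np.asarray(row_sums) + 1].sum() + lgam[c + 1].sum() - lgam[n + 1]
    if ncol == 1:
        return np.array([0.0])     # single admissible table, probability 1
    grids = np.meshgrid(*[np.arange(min(r1, cj) + 1) for cj in c[:-1]],
                        indexing="ij")
    first = np.stack([g.ravel() for g in grids], axis=1)      # (m, ncol-1)
    last = r1 - first.sum(axis=1)
    valid = (last >= 0) & (last <= c[-1])
    first = first[valid]
    last = last[valid]
    row1 = np.column_stack([first, last])
    row2 = c[None, :] - row1
    return const - lgam[row1 + 1].sum(axis=1) - lgam[row2 + 1].sum(axis=1)


def exact_symmetry_pvalues(t, alpha: float = 0.05, seed=None,
                           cap: int = 10 ** 7) -> ExactResult:
    """All five exact two-sided p-values by full enumeration.

    ``t`` is a (reduced) Q-symmetry table or a plain count matrix.  Tables
    whose probability ties the observed one within relative tolerance
    1e-12 are included in the inclusive sum, as the definition requires.
    ``alpha`` is needed only for the Tocher-randomized decision; the
    uniform draw and seed are reported, never silent.
    """
    counts = _counts_of(t)
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    if np.any(r <= 0) or np.any(c < 0):
        raise ValueError("margins must be positive")
    if counts.shape[0] > 2:
        n_est = _count_tables(r, c)
        if n_est > cap:
            raise ValueError(
                f"{n_est} tables exceed cap {cap} for a {counts.shape[0]}-row "
                "table; use exact_symmetry_montecarlo")
    log_pt = _log_table_probability(counts)
    p_t = float(np.exp(log_pt))
    thresh = log_pt + np.log1p(_REL_TOL)
    if counts.shape[0] == 2:
        lps = _log_probs_2xc(r, c)
        n_enum = len(lps)
        p_inc = float(np.exp(lps[lps <= thresh]).sum())
    else:
        p_inc = 0.0
        n_enum = 0
        for tab in enumerate_tables(r, c, cap=cap):
            n_enum += 1
            lp = _log_table_probability(tab)
            if lp <= thresh:
                p_inc += np.exp(lp)
    p_inc = min(1.0, p_inc)
    rng = np.random.default_rng(seed)
    v = _variants(p_t, p_inc, alpha, rng)
    return ExactResult(p_t=p_t, p_inc=p_inc, alpha=alpha, seed=seed,
                       n_tables_enumerated=n_enum, **v)


def exact_symmetry_montecarlo(t, B: int = 10000, alpha: float = 0.05,
                              seed=None) -> ExactResult:
    """Monte Carlo estimate of the exact p-values for large tables.

    Samples B tables from the fixed-margin null distribution by randomly
    pairing row labels with column labels (a uniformly random permutation
    induces the multiple hypergeometric law) and estimates P(f <= p_t).
    """
    if B < 1000:
        raise ValueError("B >= 1000 required for stable estimates")
    counts = _counts_of(t)
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    n = int(counts.sum())
    nrow, ncol = counts.shape
    log_pt = _log_table_probability(counts)
    p_t = float(np.exp(log_pt))
    thresh = log_pt + np.log1p(_REL_TOL)

    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(nrow), r)
    col_labels = np.repeat(np.arange(ncol), c)
    hits = 0
    lgam_tab = gammaln(np.arange(n + 2))
    const = lgam_tab[r + 1].sum() + lgam_tab[c + 1].sum() - lgam_tab[n + 1]
    for _ in range(B):
        perm = rng.permutation(col_labels)
        flat = row_labels * ncol + perm
        tab = np.bincount(flat, minlength=nrow * ncol)
        lp = const - lgam_tab[tab + 1].sum()
        if lp <= thresh:
            hits += 1
    p_inc = hits / B
    se = float(np.sqrt(p_inc * (1 - p_inc) / B))
    v = _variants(p_t, p_inc, alpha, rng)
    return ExactResult(p_t=p_t, p_inc=p_inc, alpha=alpha, seed=seed,
                       n_tables_enumerated=B, monte_carlo=True,
                       standard_errors={"p_inc": se, "p_exc": se}, **v)
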