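"""Pielou's symmetry tests.

First type — symmetry in the *mixed* NN structure (off-diagonal NNCT
cells): McNemar's chi-square on (N_12, N_21) for two classes, Bowker's
extension over all class pairs, and the exact binomial version
N_12 ~ BIN(n_t, 1/2) given n_t = N_12 + N_21.  These tests assume a
random sample of base-NN pairs (sparse sampling); on completely mapped
data the base-NN pairs are spatially dependent and the tests are
extremely conservative — every result from this family carries a standing
warning recommending the Monte Carlo randomization version instead
(:func:`nnsym.simulate.randomization_pvalue`).

Second type — symmetry in the *shared* NN structure: Pearson's chi-square
on the (reduced) Q-symmetry table, which behaves at the nominal level for
completely mapped data as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .tables import NNCT, QSymmetryTable

__all__ = [
    "TestResult",
    "CONSERVATIVE_WARNING",
    "mcnemar_symmetry",
    "binomial_symmetry",
    "bowker_symmetry",
    "pielou_q_symmetry",
]

CONSERVATIVE_WARNING = (
    "Pielou's first type of symmetry test assumes sparsely sampled base-NN "
    "pairs; for completely mapped data it is extremely conservative with "
    "asymptotic critical values. Prefer the Monte Carlo randomization "
    "version (simulate.randomization_pvalue)."
)


@dataclass
class TestResult:
    """Outcome of a symmetry test.

    ``extras`` holds method-specific quantities (n_t, per-pair components,
    randomization metadata such as seed and B, ...).
    """

    statistic: float
    p_value: float
    method: str
    df: Optional[int] = None
    sidedness: str = "two-sided"
    warnings: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValueError("df must be >= 1 when present")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic), "df": self.df,
            "p_value": float(self.p_value), "method": self.method,
            "sidedness": self.sidedness, "warnings": list(self.warnings),
            "extras": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.extras.items()},
        }


def mcnemar_symmetry(n12: int, n21: int, correction: bool = True) -> TestResult:
    """McNemar's test of E[N_12] = E[N_21], chi-square with 1 df.

    With the continuity correction the statistic is
    ``(|n12 - n21| - 1)^2 / (n12 + n21)``; without, ``(n12 - n21)^2 / n_t``.
    """
    n_t = n12 + n21
    if n_t < 1:
        raise ValueError("no mixed NN pairs (n12 + n21 = 0)")
    diff = abs(n12 - n21)
    num = (diff - 1) ** 2 if correction else diff ** 2
    if correction and diff == 0:
        # |0| - 1 squared: statistic 1/n_t by direct evaluation
        num = 1.0
    stat = num / n_t
    if not correction and diff == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(stat, 1))
    return TestResult(
        statistic=stat, df=1, p_value=p,
        method="Pielou I (McNemar symmetry)" + ("" if correction else ", uncorrected"),
        warnings=[CONSERVATIVE_WARNING],
        extras={"n_t": n_t, "correction": correction},
    )


def binomial_symmetry(n12: int, n21: int, sidedness: str = "two-sided",
                      doubled: bool = False) -> TestResult:
    """Exact version of Pielou's first test: N_12 ~ BIN(n_t, 1/2).

    The two-sided p-value sums the probabilities of all outcomes no more
    probable than the observed one (point-probability definition); with
    ``doubled=True`` the doubled smaller one-tail probability is used
    instead.  ``extras`` carries the normal-approximation statistic Z_I
    and its p-value.
    """
    n_t = n12 + n21
    if n_t < 1:
        raise ValueError("no mixed NN pairs (n12 + n21 = 0)")
    x = np.arange(n_t + 1)
    pmf = stats.binom.pmf(x, n_t, 0.5)
    p_obs = pmf[n12]
    if sidedness == "two-sided":
        if doubled:
            p = 2.0 * min(stats.binom.cdf(n12, n_t, 0.5),
                          stats.binom.sf(n12 - 1, n_t, 0.5))
        else:
            p = pmf[pmf <= p_obs * (1 + 1e-12)].sum()
        p = min(1.0, float(p))
    elif sidedness == "greater":
        p = float(stats.binom.sf(n12 - 1, n_t, 0.5))
    elif sidedness == "less":
        p = float(stats.binom.cdf(n12, n_t, 0.5))
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    z = (n12 - n21) / np.sqrt(n_t)
    if sidedness == "two-sided":
        p_norm = 2 * float(stats.norm.sf(abs(z)))
    elif sidedness == "greater":
        p_norm = float(stats.norm.sf(z))
    else:
        p_norm = float(stats.norm.cdf(z))
    return TestResult(
        statistic=float(n12), p_value=p,
        method="Pielou I (exact binomial)", sidedness=sidedness,
        warnings=[CONSERVATIVE_WARNING],
        extras={"n_t": n_t, "Z_I": float(z), "p_normal": min(1.0, p_norm)},
    )


def bowker_symmetry(t: NNCT, correction: bool = True) -> TestResult:
    """Bowker's test of symmetry over all off-diagonal NNCT pairs.

    Pairs with ``N_ij + N_ji = 0`` contribute 0/0 and are dropped from the
    statistic and from the degrees of freedom (structural-zero convention).
    """
    if t.k < 2:
        raise ValueError("at least 2 classes required")
    N = t.counts
    stat = 0.0
    df = 0
    components = {}
    for i in range(t.k):
        for j in range(i + 1, t.k):
            tot = N[i, j] + N[j, i]
            if tot == 0:
                continue
            diff = abs(int(N[i, j]) - int(N[j, i]))
            num = (diff - 1) ** 2 if correction else diff ** 2
            if correction and diff == 0:
                num = 1.0
            stat += num / tot
            df += 1
            components[f"{t.classes[i]}|{t.classes[j]}"] = num / tot
    if df == 0:
        raise ValueError("all off-diagonal pairs are empty")
    p = float(stats.chi2.sf(stat, df))
    return TestResult(
        statistic=stat, df=df, p_value=p,
        method="Pielou I (Bowker symmetry)" + ("" if correction else ", uncorrected"),
        warnings=[CONSERVATIVE_WARNING],
        extras={"components": components, "correction": correction},
    )


def pielou_q_symmetry(t: QSymmetryTable) -> TestResult:
    """Pearson chi-square on the Q-symmetry table (Pielou's second test).

    Expected counts are ``n_i * Q_m / n`` (row sum x column sum / total).
    Columns with zero total carry no information and are dropped, reducing
    the degrees of freedom ``(k-1)(c-1)`` accordingly.
    """
    if t.k < 2:
        raise ValueError("at least 2 classes required")
    counts = t.counts.astype(float)
    col = counts.sum(axis=0)
    warns = []
    if np.any(col == 0):
        warns.append(f"dropped {int((col == 0).sum())} zero-total column(s)")
        counts = counts[:, col > 0]
    n = counts.sum()
    e = np.outer(counts.sum(1), counts.sum(0)) / n
    stat = float(((counts - e) ** 2 / e).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    if df < 1:
        raise ValueError("degenerate table: fewer than 2 informative columns")
    p = float(stats.chi2.sf(stat, df))
    return TestResult(
        statistic=stat, df=df, p_value=p,
        method="Pielou II (Q-symmetry chi-square)",
        warnings=warns,
        extras={"expected": e, "reduced": t.reduced,
                "merge_boundary": t.merge_boundary},
    )
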