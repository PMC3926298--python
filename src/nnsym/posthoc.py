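"""Multiclass workflow: overall tests plus post hoc comparisons.

After a significant overall symmetry test with k > 2 classes, two post
hoc families localize the asymmetry:

* pairwise tests, *unrestricted* (extract the (i, j) cells / rows from
  the full-pattern tables and keep the full pattern's n, Q, R in the
  variance) or *restricted* (rebuild the NN digraph and tables from the
  two classes alone);
* one-versus-rest tests (pool all other classes into "rest" on the full
  geometry; only the labels change, the digraph does not).

Raw p-values are reported by default, matching common practice for these
tests; Holm adjustment is available by flag.  The choice of post hoc
family is guidance, not enforcement: unrestricted pairwise tests are the
natural follow-up to a significant overall test (they use the same data),
one-versus-rest tests are the more interpretable choice for shared-NN
asymmetry of one class against the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dixon import RLMoments, dixon_overall, dixon_z_pairwise
from .fisher_exact import exact_symmetry_pvalues
from .nn_core import PointPattern, nearest_neighbors
from .pielou import bowker_symmetry, mcnemar_symmetry, pielou_q_symmetry
from .tables import NNCT, QSymmetryTable, build_nnct, build_qsym, reduce_qsym

__all__ = ["PosthocReport", "overall_tests", "pairwise_tests",
           "one_vs_rest_tests", "holm_adjust"]

DEFAULT_TESTS = ("dixon", "pielou_I", "pielou_II", "fisher")


@dataclass
class PosthocReport:
    overall: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    mode: str = ""
    adjustment: Optional[str] = None

    def to_dict(self) -> dict:
        def conv(v):
            if hasattr(v, "to_dict"):
                return v.to_dict()
            return v
        return {
            "mode": self.mode, "adjustment": self.adjustment,
            "overall": {k: conv(v) for k, v in self.overall.items()},
            "comparisons": [
                {**{k: conv(v) for k, v in comp.items()}}
                for comp in self.comparisons
            ],
        }


def holm_adjust(pvals):
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _two_class_tests(nnct: NNCT, qsym: QSymmetryTable, mom: RLMoments,
                     tests, alpha, seed) -> dict:
    out = {}
    n12, n21 = int(nnct.counts[0, 1]), int(nnct.counts[1, 0])
    if "dixon" in tests:
        out["dixon_z"] = dixon_z_pairwise(nnct, mom, 0, 1)
    if "pielou_I" in tests:
        out["pielou_I"] = mcnemar_symmetry(n12, n21, correction=True)
        out["pielou_I_unc"] = mcnemar_symmetry(n12, n21, correction=False)
    if "pielou_II" in tests:
        out["pielou_II"] = pielou_q_symmetry(qsym)
    if "fisher" in tests:
        out["fisher"] = exact_symmetry_pvalues(qsym, alpha=alpha, seed=seed)
    return out


def overall_tests(pattern: PointPattern, tests=DEFAULT_TESTS,
                  alpha: float = 0.05, seed=None) -> dict:
    """Overall symmetry tests on the full multiclass pattern."""
    g = nearest_neighbors(pattern)
    nnct = build_nnct(pattern, g)
    qsym = reduce_qsym(build_qsym(pattern, g))
    mom = RLMoments(pattern.class_sizes, g.Q, g.R)
    out = {}
    if "dixon" in tests:
        out["dixon"] = dixon_overall(nnct, mom)
    if "pielou_I" in tests:
        out["pielou_I"] = bowker_symmetry(nnct, correction=True)
        out["pielou_I_unc"] = bowker_symmetry(nnct, correction=False)
    if "pielou_II" in tests:
        out["pielou_II"] = pielou_q_symmetry(qsym)
    if "fisher" in tests:
        try:
            out["fisher"] = exact_symmetry_pvalues(qsym, alpha=alpha, seed=seed)
        except ValueError:
            from .fisher_exact import exact_symmetry_montecarlo
            out["fisher"] = exact_symmetry_montecarlo(qsym, alpha=alpha,
                                                      seed=seed)
    return out


def pairwise_tests(pattern: PointPattern, mode: str = "unrestricted",
                   tests=DEFAULT_TESTS, alpha: float = 0.05, seed=None,
                   adjust: bool = False) -> PosthocReport:
    """All k(k-1)/2 pairwise symmetry tests.

    Unrestricted: sub-tables extracted from the full-pattern NNCT /
    Q-symmetry table, with the full pattern's n, Q, R in Dixon's variance.
    Restricted: digraph and tables rebuilt from each two-class subset.
    For k = 2 both modes coincide with the two-class tests.
    """
    if mode not in ("restricted", "unrestricted"):
        raise ValueError(f"unknown mode {mode!r}")
    g = nearest_neighbors(pattern)
    nnct = build_nnct(pattern, g)
    qsym = reduce_qsym(build_qsym(pattern, g))
    mom = RLMoments(pattern.class_sizes, g.Q, g.R)
    report = PosthocReport(mode=f"pairwise-{mode}")
    report.overall = overall_tests(pattern, tests, alpha, seed)
    classes = pattern.classes
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            if mode == "unrestricted":
                sub_nnct = NNCT(nnct.counts[np.ix_([i, j], [i, j])],
                                [classes[i], classes[j]])
                sub_qsym = QSymmetryTable(qsym.counts[[i, j]],
                                          [classes[i], classes[j]],
                                          reduced=qsym.reduced,
                                          merge_boundary=qsym.merge_boundary)
                res = {}
                if "dixon" in tests:
                    res["dixon_z"] = dixon_z_pairwise(nnct, mom, i, j)
                if "pielou_I" in tests:
                    n12 = int(nnct.counts[i, j])
                    n21 = int(nnct.counts[j, i])
                    res["pielou_I"] = mcnemar_symmetry(n12, n21, True)
                    res["pielou_I_unc"] = mcnemar_symmetry(n12, n21, False)
                if "pielou_II" in tests:
                    res["pielou_II"] = pielou_q_symmetry(sub_qsym)
                if "fisher" in tests:
                    res["fisher"] = exact_symmetry_pvalues(sub_qsym,
                                                           alpha=alpha,
                                                           seed=seed)
            else:
                sub = pattern.subset([classes[i], classes[j]])
                if sub.k < 2:
                    raise ValueError("pair with an empty class")
                gs = nearest_neighbors(sub)
                sub_nnct = build_nnct(sub, gs)
                sub_qsym = reduce_qsym(build_qsym(sub, gs))
                sub_mom = RLMoments(sub.class_sizes, gs.Q, gs.R)
                res = _two_class_tests(sub_nnct, sub_qsym, sub_mom, tests,
                                       alpha, seed)
            report.comparisons.append({
                "pair": (classes[i], classes[j]), "results": res,
                "nnct": sub_nnct, "qsym": sub_qsym,
            })
    if adjust:
        _apply_holm(report)
    return report


def one_vs_rest_tests(pattern: PointPattern, tests=DEFAULT_TESTS,
                      alpha: float = 0.05, seed=None,
                      adjust: bool = False) -> PosthocReport:
    """One-versus-rest tests: pool all other classes, full geometry kept."""
    report = PosthocReport(mode="one-vs-rest")
    report.overall = overall_tests(pattern, tests, alpha, seed)
    labels = np.asarray(pattern.labels)
    for cls in pattern.classes:
        pooled = np.where(labels == cls, str(cls), "rest")
        pooled_pat = pattern.relabel(pooled, class_order=[str(cls), "rest"])
        g = nearest_neighbors(pooled_pat)  # geometry identical to original
        nnct = build_nnct(pooled_pat, g)
        qsym = reduce_qsym(build_qsym(pooled_pat, g))
        mom = RLMoments(pooled_pat.class_sizes, g.Q, g.R)
        res = _two_class_tests(nnct, qsym, mom, tests, alpha, seed)
        report.comparisons.append({
            "pair": (str(cls), "rest"), "results": res,
            "nnct": nnct, "qsym": qsym,
        })
    if adjust:
        _apply_holm(report)
    return report


def _apply_holm(report: PosthocReport) -> None:
    report.adjustment = "holm"
    by_test = {}
    for comp in report.comparisons:
        for name, res in comp["results"].items():
            p = res.p_value if hasattr(res, "p_value") else res.p_exc
            by_test.setdefault(name, []).append((comp, p))
    for name, items in by_test.items():
        adj = holm_adjust([p for _, p in items])
        for (comp, _), a in zip(items, adj):
            comp.setdefault("adjusted_p", {})[name] = float(a)
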