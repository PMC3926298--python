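"""Pattern generators and the Monte Carlo harness.

Generators cover the null patterns (CSR independence; random labeling
over uniform or Matérn-cluster backgrounds) and six families of
alternative / structured patterns on the unit square:

* Case I   — class X uniform, class Y bivariate normal around the center
  (sd sigma): segregation by differing local intensity;
* Case II  — each Y attached, with probability p, to a randomly picked X
  with polar jitter of radius uniform on (0, that X's NN distance among
  the X points): association of Y with X;
* Case III — X uniform on (0, 1-s)^2, Y uniform on (s, 1)^2: segregation
  by shifted supports;
* Case IV  — half of each class iid on its support, the other half
  displaced from its partner by a fixed radius r at a uniform angle: an
  abundance of self-reflexive pairs;
* Case V   — Y_j placed at fixed radius r from X_j at a uniform angle:
  paired association;
* Case VI  — a three-stage construction (parameters rho, m_1, m_2)
  producing unequal off-diagonal NNCT means, i.e. asymmetry in the mixed
  NN structure, with n_1 = n_2 = m_1 + 2 m_2.

Displaced points may fall outside the unit square; no clipping is applied
anywhere (none of the tests uses the window).

The harness estimates empirical rejection rates with the asymptotic
critical values (statistic above the chi-square / normal 1-alpha point;
exact tests reject when p < alpha) and provides the label-randomization
p-value for any named test on a fixed pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .dixon import RLMoments, dixon_overall, dixon_z_pairwise
from .fisher_exact import exact_symmetry_pvalues
from .nn_core import NNDigraph, PointPattern, nearest_neighbors
from .pielou import (TestResult, bowker_symmetry, binomial_symmetry,
                     mcnemar_symmetry, pielou_q_symmetry)
from .tables import build_nnct, build_qsym, reduce_qsym

logger = logging.getLogger("nnsym")

__all__ = [
    "PatternSpec",
    "generate",
    "randomization_pvalue",
    "empirical_rejection_rate",
    "rl_empirical_size",
    "TEST_NAMES",
]

FAMILIES = ("csr", "rl-uniform", "rl-matern", "caseI", "caseII", "caseIII",
            "caseIV", "caseV", "caseVI")


@dataclass
class PatternSpec:
    """A named pattern family plus its parameters.

    Parameters by family (all on the unit square unless noted):

    - ``csr`` / ``rl-uniform``: n1, n2;
    - ``rl-matern``: kappa (parent intensity), mu (mean offspring per
      parent), r_cluster (cluster radius);
    - ``caseI``: n1, n2, sigma;
    - ``caseII``: n1, n2, p (attachment probability);
    - ``caseIII``: n1, n2, s (support shift, in (0, 1));
    - ``caseIV``: n1, n2 (even), r, supports s1, s2 as
      (xmin, xmax, ymin, ymax);
    - ``caseV``: n1, n2 (n2 <= n1), r;
    - ``caseVI``: rho (jitter fraction), m1, m2.
    """

    family: str
    n1: int = 40
    n2: int = 40
    sigma: float = 0.1
    p: float = 0.5
    s: float = 1 / 6
    r: float = 1 / 7
    rho: float = 1 / 3
    m1: int = 20
    m2: int = 10
    kappa: float = 4.0
    mu: float = 25.0
    r_cluster: float = 0.1
    s1: tuple = (0.0, 1.0, 0.0, 1.0)
    s2: tuple = (0.0, 1.0, 0.0, 1.0)
    window: tuple = (0.0, 1.0, 0.0, 1.0)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")
        if self.family == "caseIII" and not (0.0 < self.s < 1.0):
            raise ValueError("s must be in (0, 1)")
        if self.family in ("caseIV", "caseV") and not (0.0 < self.r < 1.0):
            raise ValueError("r must be in (0, 1)")
        if self.family == "caseVI" and self.rho <= 0:
            raise ValueError("rho must be positive")


def _uniform(rng, n, box=(0.0, 1.0, 0.0, 1.0)):
    xmin, xmax, ymin, ymax = box
    pts = rng.uniform(size=(n, 2))
    pts[:, 0] = xmin + pts[:, 0] * (xmax - xmin)
    pts[:, 1] = ymin + pts[:, 1] * (ymax - ymin)
    return pts


def _polar(rng, radii):
    theta = rng.uniform(0, 2 * np.pi, size=len(radii))
    return np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])


def _nn_dist(pts):
    from scipy.spatial.distance import cdist

    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def generate(spec: PatternSpec, seed=None) -> PointPattern:
    """Draw one labeled point pattern from the family in ``spec``.

    Deterministic given (spec, seed).  Class labels are "X" and "Y" in
    that order.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = spec.family

    if f in ("csr", "rl-uniform"):
        x = _uniform(rng, spec.n1)
        y = _uniform(rng, spec.n2)
    elif f == "rl-matern":
        while True:
            n_parents = rng.poisson(spec.kappa)
            if n_parents == 0:
                continue
            parents = _uniform(rng, n_parents)
            counts = rng.poisson(spec.mu, size=n_parents)
            n = int(counts.sum())
            if n < 4:
                logger.info("Matérn realization with n=%d < 4 redrawn", n)
                continue
            radii = spec.r_cluster * np.sqrt(rng.uniform(size=n))
            pts = np.repeat(parents, counts, axis=0) + _polar(rng, radii)
            n1 = n // 2
            labels = np.array(["X"] * n1 + ["Y"] * (n - n1))
            return PointPattern(coords=pts, labels=labels,
                                window=spec.window, class_order=["X", "Y"])
    elif f == "caseI":
        x = _uniform(rng, spec.n1)
        y = rng.normal(loc=0.5, scale=spec.sigma, size=(spec.n2, 2))
    elif f == "caseII":
        x = _uniform(rng, spec.n1)
        dx = _nn_dist(x)
        y = _uniform(rng, spec.n2)
        attach = rng.uniform(size=spec.n2) < spec.p
        idx = rng.integers(0, spec.n1, size=spec.n2)
        radii = rng.uniform(0, dx[idx])
        jittered = x[idx] + _polar(rng, radii)
        y[attach] = jittered[attach]
    elif f == "caseIII":
        x = _uniform(rng, spec.n1, (0, 1 - spec.s, 0, 1 - spec.s))
        y = _uniform(rng, spec.n2, (spec.s, 1, spec.s, 1))
    elif f == "caseIV":
        if spec.n1 % 2 or spec.n2 % 2:
            raise ValueError("caseIV requires even class sizes")
        hx, hy = spec.n1 // 2, spec.n2 // 2
        xb = _uniform(rng, hx, spec.s1)
        yb = _uniform(rng, hy, spec.s2)
        x = np.vstack([xb, xb + _polar(rng, np.full(hx, spec.r))])
        y = np.vstack([yb, yb + _polar(rng, np.full(hy, spec.r))])
    elif f == "caseV":
        if spec.n2 > spec.n1:
            raise ValueError("caseV requires n2 <= n1 (Y_j paired with X_j)")
        x = _uniform(rng, spec.n1)
        y = x[: spec.n2] + _polar(rng, np.full(spec.n2, spec.r))
    elif f == "caseVI":
        # Three-stage asymmetric-association construction.  Stage 1 pairs
        # Y_i tightly with X_i (i <= m1); stage 2 pairs an extra X' with
        # each of X_{m1+1..m1+m2}; both jitters are uniform on
        # (0, rho * own NN distance among the X backbone).  The remaining
        # 2*m2 Y points are unassociated (uniform): tightening rho then
        # drives N_21 up (every stage-1 Y has an X nearest neighbor) while
        # N_12 stays near m1, so the off-diagonal NNCT cells separate.
        m1, m2, rho = spec.m1, spec.m2, spec.rho
        xb = _uniform(rng, m1 + m2)
        dx = _nn_dist(xb)
        y1 = xb[:m1] + _polar(rng, rng.uniform(0, rho * dx[:m1]))
        x2 = xb[m1:] + _polar(rng, rng.uniform(0, rho * dx[m1:]))
        yp = _uniform(rng, m2)
        y3 = _uniform(rng, m2)
        x = np.vstack([xb, x2])
        y = np.vstack([y1, yp, y3])
    else:  # pragma: no cover
        raise ValueError(f"unknown family {f!r}")

    labels = np.array(["X"] * len(x) + ["Y"] * len(y))
    return PointPattern(coords=np.vstack([x, y]), labels=labels,
                        window=spec.window, class_order=["X", "Y"])


# ---------------------------------------------------------------------------
# named tests for the harness
# ---------------------------------------------------------------------------

def _ctx(pattern: PointPattern, g: NNDigraph):
    nnct = build_nnct(pattern, g)
    qsym = reduce_qsym(build_qsym(pattern, g))
    mom = RLMoments(pattern.class_sizes, g.Q, g.R)
    return nnct, qsym, mom


def _stat_pielou_I(pattern, g, nnct, qsym, mom, corrected=True):
    if nnct.k == 2:
        r = mcnemar_symmetry(int(nnct.counts[0, 1]), int(nnct.counts[1, 0]),
                             correction=corrected)
    else:
        r = bowker_symmetry(nnct, correction=corrected)
    return r.statistic, r.df or 1


def _reject_chi2(stat, df, alpha):
    return alpha >= 1.0 or stat > stats.chi2.ppf(1 - alpha, df)


def _run_test(name, pattern, g, nnct, qsym, mom, alpha, rng):
    """Return (statistic, reject?) for one named test on one replicate."""
    if name == "pielou_I":
        s, df = _stat_pielou_I(pattern, g, nnct, qsym, mom, True)
        return s, _reject_chi2(s, df, alpha)
    if name == "pielou_I_unc":
        s, df = _stat_pielou_I(pattern, g, nnct, qsym, mom, False)
        return s, _reject_chi2(s, df, alpha)
    if name == "binomial":
        r = binomial_symmetry(int(nnct.counts[0, 1]), int(nnct.counts[1, 0]))
        return r.statistic, r.p_value < alpha
    if name == "dixon_z":
        r = dixon_z_pairwise(nnct, mom, 0, 1)
        return r.statistic, abs(r.statistic) > stats.norm.ppf(1 - alpha / 2)
    if name == "dixon_overall":
        r = dixon_overall(nnct, mom)
        return r.statistic, _reject_chi2(r.statistic, r.df, alpha)
    if name == "pielou_II":
        r = pielou_q_symmetry(qsym)
        return r.statistic, _reject_chi2(r.statistic, r.df, alpha)
    if name.startswith("fisher_"):
        res = exact_symmetry_pvalues(qsym, alpha=alpha,
                                     seed=rng.integers(2 ** 31))
        p = {"fisher_exc": res.p_exc, "fisher_inc": res.p_inc,
             "fisher_mid": res.p_mid, "fisher_toc": res.p_toc,
             "fisher_tinc": res.p_t_inc}[name]
        return p, p < alpha
    raise ValueError(f"unknown test {name!r}")


TEST_NAMES = ("pielou_I", "pielou_I_unc", "binomial", "dixon_z",
              "dixon_overall", "pielou_II", "fisher_exc", "fisher_inc",
              "fisher_mid", "fisher_toc", "fisher_tinc")


def randomization_pvalue(pattern: PointPattern, statistic: str, B: int = 999,
                         seed=None) -> TestResult:
    """Label-randomization p-value for a named test on a fixed pattern.

    Class labels are permuted B times over the fixed locations (the NN
    digraph is geometry-only and unchanged); the p-value is the rank of
    the observed statistic, (1 + #{T_b >= T_obs}) / (B + 1).  For Dixon's
    Z the two-sided |Z| is ranked.
    """
    if B < 99:
        raise ValueError("B >= 99 required")
    if statistic == "binomial":
        raise ValueError("the binomial test conditions on n_t, which is not "
                         "fixed under randomization")
    rng = np.random.default_rng(seed)
    g = nearest_neighbors(pattern)

    def observed_stat(pat):
        nnct, qsym, mom = _ctx(pat, g)
        s, _ = _run_test(statistic, pat, g, nnct, qsym, mom, 0.05, rng)
        return abs(s) if statistic == "dixon_z" else s

    t_obs = observed_stat(pattern)
    labels = np.asarray(pattern.labels)
    count = 0
    dropped = 0
    for _ in range(B):
        perm = pattern.relabel(rng.permutation(labels),
                               class_order=pattern.classes)
        try:
            t_b = observed_stat(perm)
        except (ValueError, ZeroDivisionError):
            dropped += 1
            logger.warning("statistic undefined on a relabeling; dropped")
            continue
        if t_b >= t_obs:
            count += 1
    b_eff = B - dropped
    p = (1 + count) / (b_eff + 1)
    warns = [f"{dropped} relabelings dropped"] if dropped else []
    return TestResult(
        statistic=float(t_obs), p_value=p,
        method=f"randomization[{statistic}]", warnings=warns,
        extras={"B": B, "B_effective": b_eff, "seed": seed},
    )


def empirical_rejection_rate(spec: PatternSpec, tests, N_mc: int = 10000,
                             alpha: float = 0.05, seed=None) -> dict:
    """Empirical rejection rates of the named tests under ``spec``.

    Each replicate draws a fresh pattern; chi-square / normal tests use
    their asymptotic critical values, exact tests their p-values.  Returns
    per-test rates with binomial Monte Carlo standard errors plus the
    mean/SD summaries of N_12, N_21 and N_12 - N_21.
    """
    if N_mc < 100:
        raise ValueError("N_mc >= 100 required")
    if isinstance(tests, str):
        tests = [tests]
    tests = list(tests)
    rng = np.random.default_rng(seed)
    rejects = {t: 0 for t in tests}
    n12 = np.empty(N_mc)
    n21 = np.empty(N_mc)
    for b in range(N_mc):
        pat = generate(spec, rng)
        g = nearest_neighbors(pat)
        nnct, qsym, mom = _ctx(pat, g)
        n12[b] = nnct.counts[0, 1]
        n21[b] = nnct.counts[1, 0]
        for t in tests:
            _, rej = _run_test(t, pat, g, nnct, qsym, mom, alpha, rng)
            rejects[t] += bool(rej)
    out = {"N_mc": N_mc, "alpha": alpha, "seed": seed,
           "family": spec.family,
           "N_12": {"mean": float(n12.mean()), "sd": float(n12.std(ddof=1))},
           "N_21": {"mean": float(n21.mean()), "sd": float(n21.std(ddof=1))},
           "N_12-N_21": {"mean": float((n12 - n21).mean()),
                         "sd": float((n12 - n21).std(ddof=1))},
           "tests": {}}
    for t in tests:
        rate = rejects[t] / N_mc
        out["tests"][t] = {"rate": rate,
                           "mc_se": float(np.sqrt(rate * (1 - rate) / N_mc))}
    return out


def rl_empirical_size(spec: PatternSpec, tests, n_backgrounds: int = 100,
                      n_relabel: int = 1000, alpha: float = 0.05,
                      seed=None) -> dict:
    """Empirical size under random labeling of fixed backgrounds.

    Draws ``n_backgrounds`` background patterns from ``spec`` and, for
    each, relabels the points ``n_relabel`` times with the class sizes
    fixed, recomputing only the label-dependent tables (the digraph and
    hence Q, R stay fixed per background).
    """
    if isinstance(tests, str):
        tests = [tests]
    tests = list(tests)
    rng = np.random.default_rng(seed)
    rejects = {t: 0 for t in tests}
    total = 0
    for _ in range(n_backgrounds):
        pat = generate(spec, rng)
        g = nearest_neighbors(pat)
        labels = np.asarray(pat.labels)
        for _ in range(n_relabel):
            rl = pat.relabel(rng.permutation(labels), class_order=pat.classes)
            nnct, qsym, mom = _ctx(rl, g)
            for t in tests:
                try:
                    _, rej = _run_test(t, rl, g, nnct, qsym, mom, alpha, rng)
                except ValueError:
                    continue
                rejects[t] += bool(rej)
            total += 1
    return {"tests": {t: {"rate": rejects[t] / total,
                          "mc_se": float(np.sqrt(rejects[t] / total
                                                 * (1 - rejects[t] / total)
                                                 / total))}
                      for t in tests},
            "n_replicates": total, "alpha": alpha, "seed": seed}
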