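"""Asymptotic power utilities: local power and Pitman efficiencies.

For a statistic converging to chi-square with ``nu`` df and noncentrality
``lam`` under local alternatives, the power near the null expands as

    beta(lam, nu, alpha) ~ alpha
        + lam * ( -alpha/2 + (1/2) * [1 - F_{nu+2}( chi2_nu(1-alpha) )] ),

with F the *central* chi-square cdf with nu + 2 df evaluated at the
central nu-df critical value.  This is a first-order expansion in lam,
valid for small noncentrality only.

Pitman asymptotic efficiency (PAE) is lim mu'(0)^2 / (n sigma^2) under a
local parameterization of the alternative.  For the exact-binomial /
McNemar statistic the PAE is the constant 4.  For the two-class Dixon
statistic, with nu_1 the class-1 proportion, p_q = E[Q/n] the probability
of a point being a shared NN and p_r = E[R/n] the probability of a pair
being reflexive, the large-n variance approximations

    Var[N_ij]/n      ~ nu_i nu_j [1 + p_q nu_i - (3 + p_q - p_r) nu_i nu_j]
    Cov[N_12,N_21]/n ~ nu_1 nu_2 [p_r + (1 - p_r)(nu_1 + nu_2)
                                  - (3 + p_q - p_r) nu_1 nu_2]

combine to PAE(Z_D) = 1 / (nu_1 (1 - nu_1) p_q): Dixon's test is locally
most efficient when the class abundances are very unequal, least when
nu_1 = 1/2.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["local_power", "pae_pielou", "pae_dixon",
           "dixon_variance_approx", "dixon_covariance_approx"]


def local_power(lam: float, nu: int, alpha: float) -> float:
    """First-order local power of a chi-square test near lam = 0."""
    if lam < 0:
        raise ValueError("noncentrality must be >= 0")
    if nu < 1:
        raise ValueError("df must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    crit = stats.chi2.ppf(1 - alpha, nu)
    bracket = -alpha / 2 + 0.5 * (1.0 - stats.chi2.cdf(crit, nu + 2))
    return float(alpha + lam * bracket)


def pae_pielou() -> dict:
    """PAE of the exact-binomial / McNemar symmetry statistic.

    With T = N_12/n_t - 1/2 and the alternative N_12 ~ BIN(n_t, 1/2 + eps),
    mu'(0) = 1 and sigma^2 = 1/(4 n_t), so the efficiency is 4,
    independent of n_t.
    """
    return {"pae": 4.0, "mu_prime_0": 1.0, "sigma2": "1/(4 n_t)"}


def dixon_variance_approx(nu_i: float, nu_j: float, p_q: float,
                          p_r: float) -> float:
    """Large-n Var[N_ij]/n under RL."""
    return nu_i * nu_j * (1 + p_q * nu_i - (3 + p_q - p_r) * nu_i * nu_j)


def dixon_covariance_approx(nu_1: float, nu_2: float, p_q: float,
                            p_r: float) -> float:
    """Large-n Cov[N_12, N_21]/n under RL."""
    return nu_1 * nu_2 * (p_r + (1 - p_r) * (nu_1 + nu_2)
                          - (3 + p_q - p_r) * nu_1 * nu_2)


def pae_dixon(nu_1: float, p_q: float, p_r: float | None = None) -> float:
    """PAE of the two-class Dixon statistic, 1 / (nu_1 (1 - nu_1) p_q).

    ``p_r`` is accepted for symmetry with the variance helpers; the
    reflexivity terms cancel in Var[N_12 - N_21] and the efficiency
    depends only on nu_1 and p_q.
    """
    if not (0.0 < nu_1 < 1.0):
        raise ValueError("nu_1 on the boundary gives infinite efficiency")
    if not (0.0 < p_q <= 1.0):
        raise ValueError("p_q must be in (0, 1]")
    return 1.0 / (nu_1 * (1.0 - nu_1) * p_q)
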