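"""Independent brute-force / Monte-Carlo oracles used across the tests.

Everything here is deliberately naive O(n^2) enumeration or simulation,
kept separate from the package's fast implementations so the two routes
stay independent.
"""

from __future__ import annotations

import numpy as np


def harrell_c_brute(probs, y) -> float:
    """O(n^2) pairwise c-index with the 1/2 tie convention."""
    p = np.asarray(probs, float)
    y = np.asarray(y, int)
    num = den = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            if y[i] == 1 and y[j] == 0:
                den += 1
                if p[i] > p[j]:
                    num += 1
                elif p[i] == p[j]:
                    num += 0.5
    return num / den


def mbc_brute(probs) -> float:
    """O(n^2) unordered-pairs model-based concordance."""
    p = np.asarray(probs, float)
    n = len(p)
    num = den = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a = p[i] * (1 - p[j])
            b = p[j] * (1 - p[i])
            den += a + b
            if p[i] > p[j]:
                num += a
            elif p[j] > p[i]:
                num += b
            else:
                num += 0.5 * (a + b)
    return num / den


def expected_concordance_brute(scores, probs) -> float:
    s = np.asarray(scores, float)
    p = np.asarray(probs, float)
    n = len(p)
    num = den = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a = p[i] * (1 - p[j])
            b = p[j] * (1 - p[i])
            den += a + b
            if s[i] > s[j]:
                num += a
            elif s[j] > s[i]:
                num += b
            else:
                num += 0.5 * (a + b)
    return num / den


def mc_mean_cindex(probs, n_sims: int, rng) -> tuple:
    """Mean c-index over simulated Bernoulli(probs) outcome vectors.

    Uses the rank identity for speed (the ranking is fixed because the
    probabilities are); returns ``(mean, mc_standard_error, n_used)``,
    draws with a single outcome class discarded.
    """
    from scipy.stats import rankdata

    p = np.asarray(probs, float)
    n = len(p)
    ranks = rankdata(p)  # midranks
    ymat = (rng.random((n_sims, n)) < p[None, :])
    n1 = ymat.sum(axis=1)
    ok = (n1 > 0) & (n1 < n)
    ymat = ymat[ok]
    n1 = n1[ok]
    u = ymat @ ranks - n1 * (n1 + 1) / 2.0
    c = u / (n1 * (n - n1))
    return float(c.mean()), float(c.std(ddof=1) / np.sqrt(len(c))), int(len(c))


def glmm_loglik_quadrature(z_by_cluster, y_by_cluster, beta0, gamma, Sigma,
                           n_nodes: int = 80, half_width: float = 6.0) -> float:
    """Brute-force marginal log-likelihood of the 2-D random-effects
    logistic model by tensor-product quadrature over each cluster's
    random effect (trapezoid on a wide grid, transformed to the
    principal axes of Sigma)."""
    from numpy.polynomial.legendre import leggauss
    from scipy.special import expit

    w_, x_ = None, None
    x_, w_ = leggauss(n_nodes)
    total = 0.0
    evals, evecs = np.linalg.eigh(Sigma)
    evals = np.maximum(evals, 1e-12)
    for zk, yk in zip(z_by_cluster, y_by_cluster):
        zk = np.asarray(zk, float)
        yk = np.asarray(yk, float)
        # grid in standardized principal coordinates: u = V diag(sqrt(l)) t
        t = half_width * x_
        wt = half_width * w_
        T0, T1 = np.meshgrid(t, t, indexing="ij")
        W = np.outer(wt, wt)
        U = np.stack([T0.ravel(), T1.ravel()], axis=1)
        u = (evecs @ (np.sqrt(evals)[:, None] * U.T)).T
        dens = np.exp(-0.5 * (U ** 2).sum(axis=1)) / (2 * np.pi)
        eta = beta0 + gamma[0] + u[:, 0][:, None] + \
            (gamma[1] + u[:, 1])[:, None] * zk[None, :]
        ll = (yk[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        m = ll.max()
        integrand = np.exp(ll - m) * dens
        # jacobian of u = V sqrt(L) t is sqrt(det Sigma); it cancels the
        # normal density's 1/sqrt(det Sigma), leaving the standard normal
        val = (integrand * W.ravel()).sum()
        total += m + np.log(val)
    return float(total)
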