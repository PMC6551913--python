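"""Vectorized per-cluster logistic likelihood machinery.

Everything here works on data laid out cluster-contiguously (``starts``
marks the first row of each cluster, as produced by
``ClusteredDataset.sorted_by_cluster``) so that per-cluster sums reduce
to ``np.add.reduceat`` calls and the whole collection of 2-parameter
logistic problems is solved simultaneously.

Two uses share the solver:

* unpenalized (``prec=None``): independent per-cluster maximum-likelihood
  calibration fits of ``logit(p) = offset + v0 + v1 z``;
* penalized (``prec`` a 2x2 precision matrix, ``mean`` the prior mean):
  the inner step of the Laplace approximation for the multilevel model,
  where the per-cluster coefficients maximize the joint log-density
  ``loglik(v) - 0.5 (v - mean)' prec (v - mean)``.

The per-cluster objective is concave, so damped Newton with step halving
converges globally; divergence (separation) shows up as coefficients
running past ``COEF_CAP`` and is flagged, never silently truncated into a
"converged" answer.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit

COEF_CAP = 30.0  # |coefficient| beyond this on the logit scale means separation
_MAX_NEWTON = 60
_DECREMENT_TOL = 1e-13  # Newton decrement g'H^{-1}g, in log-likelihood units


def _log1pexp(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)) without overflow."""
    return np.logaddexp(0.0, x)


def grouped_logistic(z, y, offset, starts, prec=None, mean=None, v0=None,
                     max_iter: int = _MAX_NEWTON, tol: float = _DECREMENT_TOL):
    """Solve all per-cluster 2-parameter logistic problems at once.

    Parameters
    ----------
    z, y, offset : arrays over rows, cluster-contiguous.
    starts : first row index of each of the K clusters.
    prec : optional (2, 2) precision matrix of the quadratic penalty
        (shared across clusters); ``None`` for plain ML.
    mean : optional (2,) penalty center (``(gamma0, gamma1)`` for the
        multilevel inner step); defaults to zero.
    v0 : optional (K, 2) warm-start coefficients.

    Returns
    -------
    dict with keys ``v`` (K, 2 coefficients), ``ll`` (K per-cluster
    log-likelihood at the solution, penalty NOT included), ``info``
    (K, 2, 2 observed information X'WX), ``grad_norm``, ``converged``
    (K bools), ``flagged`` (K bools: separation / one-class divergence),
    ``n_iter``.
    """
    z = np.asarray(z, dtype=float)
    yf = np.asarray(y, dtype=float)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), z.shape)
    starts = np.asarray(starts)
    K = starts.size
    if mean is None:
        mean = np.zeros(2)
    mean = np.asarray(mean, dtype=float)
    penalized = prec is not None
    if penalized:
        p00, p01, p11 = float(prec[0, 0]), float(prec[0, 1]), float(prec[1, 1])

    v = np.zeros((K, 2)) if v0 is None else np.array(v0, dtype=float)
    if penalized and v0 is None:
        v[:] = mean

    def objective_and_state(v):
        eta = offset + v[:, 0].repeat(counts) + v[:, 1].repeat(counts) * z
        ll_rows = yf * eta - _log1pexp(eta)
        ll = np.add.reduceat(ll_rows, starts)
        obj = ll.copy()
        if penalized:
            d0 = v[:, 0] - mean[0]
            d1 = v[:, 1] - mean[1]
            obj -= 0.5 * (p00 * d0 * d0 + 2 * p01 * d0 * d1 + p11 * d1 * d1)
        return eta, ll, obj

    counts = np.diff(np.append(starts, z.size))
    eta, ll, obj = objective_and_state(v)
    n_iter = 0
    converged = np.zeros(K, dtype=bool)
    for n_iter in range(1, max_iter + 1):
        p = _expit(eta)
        w = p * (1.0 - p)
        r = yf - p
        g0 = np.add.reduceat(r, starts)
        g1 = np.add.reduceat(r * z, starts)
        a = np.add.reduceat(w, starts)          # X'WX elements
        b = np.add.reduceat(w * z, starts)
        c = np.add.reduceat(w * z * z, starts)
        if penalized:
            d0 = v[:, 0] - mean[0]
            d1 = v[:, 1] - mean[1]
            g0 = g0 - (p00 * d0 + p01 * d1)
            g1 = g1 - (p01 * d0 + p11 * d1)
            a = a + p00
            b = b + p01
            c = c + p11
        gnorm = np.maximum(np.abs(g0), np.abs(g1))
        det = a * c - b * b
        det = np.where(det <= 1e-300, 1e-300, det)
        s0 = (c * g0 - b * g1) / det
        s1 = (a * g1 - b * g0) / det
        # scale-invariant stop: Newton decrement in log-likelihood units
        decrement = g0 * s0 + g1 * s1
        converged = decrement < tol
        if converged.all():
            break
        # step-halving on clusters whose objective does not improve
        step = np.column_stack((s0, s1))
        scale = np.ones(K)
        for _ in range(25):
            v_try = v + scale[:, None] * step
            eta_try, ll_try, obj_try = objective_and_state(v_try)
            worse = obj_try < obj - 1e-12
            if not worse.any():
                break
            scale[worse] *= 0.5
        v, eta, ll, obj = v_try, eta_try, ll_try, obj_try
    p = _expit(eta)
    w = p * (1.0 - p)
    info = np.empty((K, 2, 2))
    info[:, 0, 0] = np.add.reduceat(w, starts)
    info[:, 0, 1] = info[:, 1, 0] = np.add.reduceat(w * z, starts)
    info[:, 1, 1] = np.add.reduceat(w * z * z, starts)
    flagged = np.abs(v).max(axis=1) > COEF_CAP
    return {
        "v": v,
        "ll": ll,
        "info": info,
        "grad_norm": gnorm if n_iter else np.zeros(K),
        "converged": converged & ~flagged,
        "flagged": flagged | ~converged,
        "n_iter": n_iter,
    }


def cov_matrix(sigma0: float, sigma1: float, rho: float) -> np.ndarray:
    return np.array([
        [sigma0 * sigma0, rho * sigma0 * sigma1],
        [rho * sigma0 * sigma1, sigma1 * sigma1],
    ])


def laplace_marginal_loglik(z, y, offset, starts, gamma, Sigma, v_warm=None):
    """Laplace-approximated marginal log-likelihood of the multilevel model.

    Per cluster k the marginal likelihood integrates the Bernoulli
    likelihood of ``logit(p) = offset + v0 + v1 z`` against the bivariate
    normal density of ``v ~ N(gamma, Sigma)``.  The Laplace approximation
    evaluates the joint log-density at its mode ``v_hat`` and corrects
    with the curvature there:

        ll_k = loglik_k(v_hat) - 0.5 d' Sigma^{-1} d
               - 0.5 log det(I + Sigma A_k),      d = v_hat - gamma

    with ``A_k`` the observed information of the logistic part at the
    mode.  The ``log det(I + Sigma A)`` form stays finite as the variance
    components approach zero (boundary fits), where it tends to 0 and the
    mode collapses onto ``gamma``.

    Returns ``(total, sol)`` where ``sol`` is the inner solver output
    (modes, per-cluster information) for reuse.
    """
    s0 = np.sqrt(Sigma[0, 0])
    s1 = np.sqrt(Sigma[1, 1])
    rho = Sigma[0, 1] / (s0 * s1) if s0 > 0 and s1 > 0 else 0.0
    rho = np.clip(rho, -0.999999, 0.999999)
    det_S = (s0 * s1) ** 2 * (1 - rho * rho)
    if det_S <= 0 or min(s0, s1) < 1e-12:
        # numerically singular prior: pin the modes to gamma
        prec = np.array([[1e24, 0.0], [0.0, 1e24]])
    else:
        prec = np.linalg.inv(Sigma)
    sol = grouped_logistic(z, y, offset, starts, prec=prec, mean=gamma, v0=v_warm)
    d = sol["v"] - gamma[None, :]
    quad = np.einsum("ki,ij,kj->k", d, prec, d)
    M = np.eye(2)[None, :, :] + Sigma[None, :, :] @ sol["info"]
    det_M = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    det_M = np.maximum(det_M, 1e-300)
    contrib = sol["ll"] - 0.5 * quad - 0.5 * np.log(det_M)
    return float(contrib.sum()), sol


def conditional_covariances(info, Sigma) -> np.ndarray:
    """Conditional (posterior) covariance of each cluster's coefficients.

    ``(A_k + Sigma^{-1})^{-1}`` computed in the stable product form
    ``(I + Sigma A_k)^{-1} Sigma`` so that a boundary ``Sigma -> 0``
    degenerates to zero covariance instead of overflowing.
    """
    K = info.shape[0]
    M = np.eye(2)[None, :, :] + Sigma[None, :, :] @ info
    out = np.empty((K, 2, 2))
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    det = np.where(np.abs(det) < 1e-300, 1e-300, det)
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1] / det
    inv[:, 1, 1] = M[:, 0, 0] / det
    inv[:, 0, 1] = -M[:, 0, 1] / det
    inv[:, 1, 0] = -M[:, 1, 0] / det
    out = inv @ Sigma[None, :, :]
    # symmetrize against round-off
    return 0.5 * (out + np.transpose(out, (0, 2, 1)))
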