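"""Cluster-specific recalibration of a logistic prediction model.

Given validation data with linear predictors ``z`` (log-odds, excluding
the original intercept ``beta0``), the calibration model per cluster k is

    logit(p_ik) = offset(beta0) + gamma0k + gamma1k * z_ik

Two estimators of the per-cluster coefficients are provided as
scikit-learn style classes:

* :class:`FixedEffectsCalibrator` — independent maximum-likelihood fits
  per cluster (unshrunk; flagged non-finite under separation or a
  single-class cluster).
* :class:`MultilevelCalibrator` — a mixed logistic model with correlated
  random intercept and random slope,

      (gamma0k, gamma1k) ~ N((gamma0, gamma1), Sigma),
      Sigma = [[s0^2, rho s0 s1], [rho s0 s1, s1^2]],

  fitted by maximizing the Laplace-approximated marginal likelihood.
  The per-cluster estimates are the conditional modes (the logistic
  analogue of BLUPs), shrunk toward the population means in proportion
  to cluster information, with conditional (posterior-mode) standard
  errors.

Both accept ``X`` as a DataFrame with ``cluster``/``lp`` columns or a
2-column array ``[cluster, lp]``, plus binary ``y``; module-level
functions :func:`fit_fixed_per_cluster` and :func:`fit_multilevel`
wrap them for use with :class:`~cmbc.data.ClusteredDataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from ._glm import (
    conditional_covariances,
    cov_matrix,
    grouped_logistic,
    laplace_marginal_loglik,
)
from .data import ClusteredDataset

__all__ = [
    "CalibrationEstimate",
    "MultilevelFit",
    "FixedEffectsCalibrator",
    "MultilevelCalibrator",
    "fit_fixed_per_cluster",
    "fit_multilevel",
]

BOUNDARY_SIGMA = 1e-4  # a fitted between-cluster SD below this is a boundary fit


@dataclass
class CalibrationEstimate:
    """One cluster's calibration intercept and slope with uncertainty."""

    cluster_id: object
    gamma0: float
    gamma1: float
    se0: float
    se1: float
    kind: str  # "fixed" | "random"
    converged: bool = True
    message: str = ""


@dataclass
class MultilevelFit:
    """Population parameters and conditional modes of the multilevel model."""

    gamma0: float
    gamma1: float
    sigma0: float
    sigma1: float
    rho: float
    estimates: list  # CalibrationEstimate, kind="random", one per cluster
    cond_cov: dict   # cluster_id -> (2, 2) conditional covariance
    loglik: float
    converged: bool
    n_iterations: int
    boundary: bool = False
    beta0: float = 0.0
    message: str = ""
    cov_re: np.ndarray = None  # fitted 2x2 random-effects covariance

    def estimate_for(self, cluster_id) -> CalibrationEstimate:
        return self._by_id[cluster_id]

    def __post_init__(self):
        self._by_id = {e.cluster_id: e for e in self.estimates}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": [e.cluster_id for e in self.estimates],
                "gamma0": [e.gamma0 for e in self.estimates],
                "gamma1": [e.gamma1 for e in self.estimates],
                "se0": [e.se0 for e in self.estimates],
                "se1": [e.se1 for e in self.estimates],
            }
        )


def _coerce_X(X):
    """Accept DataFrame (cluster/lp columns) or 2-column array."""
    if isinstance(X, pd.DataFrame):
        if "cluster" in X.columns and "lp" in X.columns:
            return X["cluster"].to_numpy(), X["lp"].to_numpy(dtype=float)
        if X.shape[1] != 2:
            raise ValueError("DataFrame X needs 'cluster' and 'lp' columns")
        return X.iloc[:, 0].to_numpy(), X.iloc[:, 1].to_numpy(dtype=float)
    arr = np.asarray(X)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("X must be (n, 2): [cluster, lp]")
    return arr[:, 0], arr[:, 1].astype(float)


class FixedEffectsCalibrator(BaseEstimator):
    """Independent per-cluster ML calibration fits with a fixed offset.

    Parameters
    ----------
    beta0 : float
        Original-model intercept, entered as an offset (never refitted).

    Attributes
    ----------
    estimates_ : pd.DataFrame
        Per-cluster ``gamma0, gamma1, se0, se1, converged`` rows; NaN
        coefficients with ``converged=False`` mark separation or
        single-class clusters.
    clusters_ : np.ndarray
    """

    def __init__(self, beta0: float = 0.0):
        self.beta0 = beta0

    def fit(self, X, y):
        cluster, z = _coerce_X(X)
        data = ClusteredDataset(cluster, z, np.asarray(y), self.beta0)
        self.estimates_list_ = _fixed_estimates(data)
        self.clusters_ = data.clusters_
        self.estimates_ = pd.DataFrame(
            {
                "cluster": [e.cluster_id for e in self.estimates_list_],
                "gamma0": [e.gamma0 for e in self.estimates_list_],
                "gamma1": [e.gamma1 for e in self.estimates_list_],
                "se0": [e.se0 for e in self.estimates_list_],
                "se1": [e.se1 for e in self.estimates_list_],
                "converged": [e.converged for e in self.estimates_list_],
            }
        )
        return self

    def predict_proba(self, X):
        from scipy.special import expit

        cluster, z = _coerce_X(X)
        lut = {e.cluster_id: (e.gamma0, e.gamma1) for e in self.estimates_list_}
        g = np.array([lut[c] for c in cluster])
        p1 = expit(self.beta0 + g[:, 0] + g[:, 1] * z)
        return np.column_stack((1 - p1, p1))


class MultilevelCalibrator(BaseEstimator):
    """Correlated random-intercept/random-slope logistic calibration model.

    Fitted by nested optimization of the Laplace-approximated marginal
    likelihood: the inner loop solves each cluster's penalized logistic
    problem for the conditional modes; the outer loop runs L-BFGS-B over
    ``(gamma0, gamma1, log sigma0, log sigma1, atanh rho)``, so the
    search is unconstrained in the variance parameters and a vanishing
    between-cluster SD is a valid boundary outcome rather than an error.

    Parameters
    ----------
    beta0 : float
        Original-model intercept (fixed offset).
    max_iter : int
        Outer iteration cap.
    gtol : float
        Outer projected-gradient tolerance.

    Attributes (after ``fit``)
    --------------------------
    gamma0_, gamma1_ : population-mean calibration intercept and slope.
    sigma0_, sigma1_, rho_ : between-cluster SDs and their correlation.
    estimates_ : pd.DataFrame of conditional modes with conditional SEs.
    result_ : MultilevelFit with the full structured output.
    """

    def __init__(self, beta0: float = 0.0, max_iter: int = 500, gtol: float = 1e-6):
        self.beta0 = beta0
        self.max_iter = max_iter
        self.gtol = gtol

    def fit(self, X, y):
        cluster, z = _coerce_X(X)
        data = ClusteredDataset(cluster, z, np.asarray(y), self.beta0)
        self.result_ = _multilevel_fit(data, max_iter=self.max_iter, gtol=self.gtol)
        r = self.result_
        self.gamma0_, self.gamma1_ = r.gamma0, r.gamma1
        self.sigma0_, self.sigma1_, self.rho_ = r.sigma0, r.sigma1, r.rho
        self.loglik_ = r.loglik
        self.converged_ = r.converged
        self.n_iter_ = r.n_iterations
        self.estimates_ = r.to_frame()
        self.clusters_ = data.clusters_
        return self

    def predict_proba(self, X):
        from scipy.special import expit

        cluster, z = _coerce_X(X)
        lut = {e.cluster_id: (e.gamma0, e.gamma1) for e in self.result_.estimates}
        g0mean, g1mean = self.gamma0_, self.gamma1_
        g = np.array([lut.get(c, (g0mean, g1mean)) for c in cluster])
        p1 = expit(self.beta0 + g[:, 0] + g[:, 1] * z)
        return np.column_stack((1 - p1, p1))


# ---------------------------------------------------------------------------
# implementation


def _fixed_estimates(data: ClusteredDataset) -> list:
    codes, z, y, starts = data.sorted_by_cluster()
    sol = grouped_logistic(z, y, data.beta0, starts)
    events = data.cluster_events().to_numpy()
    sizes = data.cluster_sizes().to_numpy()
    out = []
    for k, cid in enumerate(data.clusters_):
        one_class = events[k] == 0 or events[k] == sizes[k]
        bad = bool(sol["flagged"][k]) or one_class
        if bad:
            msg = ("single outcome class" if one_class else
                   "separation / non-convergence")
            out.append(CalibrationEstimate(cid, np.nan, np.nan, np.nan, np.nan,
                                           "fixed", converged=False, message=msg))
            continue
        info = sol["info"][k]
        cov = np.linalg.inv(info)
        out.append(CalibrationEstimate(
            cid, float(sol["v"][k, 0]), float(sol["v"][k, 1]),
            float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])), "fixed"))
    return out


def fit_fixed_per_cluster(data: ClusteredDataset) -> list:
    """Per-cluster ML calibration fits; see :class:`FixedEffectsCalibrator`."""
    return _fixed_estimates(data)


def _pooled_start(z, y, offset):
    sol = grouped_logistic(z, y, offset, np.array([0]))
    if sol["flagged"][0]:
        return np.zeros(2)
    return sol["v"][0]


def _multilevel_fit(data: ClusteredDataset, max_iter: int = 500,
                    gtol: float = 1e-6) -> MultilevelFit:
    if data.n_clusters < 2:
        raise ValueError("multilevel fit needs at least 2 clusters")
    if data.n_clusters < 10:
        warnings.warn(
            f"only {data.n_clusters} clusters: between-cluster variances are "
            "poorly identified below ~10 clusters; proceeding anyway",
            UserWarning, stacklevel=2,
        )
    codes, z, y, starts = data.sorted_by_cluster()
    offset = np.full(z.shape, data.beta0)

    g_start = _pooled_start(z, y, data.beta0)
    x0 = np.array([g_start[0], g_start[1], np.log(0.1), np.log(0.1), 0.0])
    warm = {"v": None}

    def negloglik(theta):
        gamma = theta[:2]
        s0, s1 = np.exp(theta[2]), np.exp(theta[3])
        rho = np.tanh(theta[4])
        Sigma = cov_matrix(s0, s1, rho)
        total, sol = laplace_marginal_loglik(z, y, offset, starts, gamma, Sigma,
                                             v_warm=warm["v"])
        warm["v"] = sol["v"]
        return -total

    bounds = [(None, None), (None, None),
              (np.log(1e-6), 3.0), (np.log(1e-6), 3.0), (-6.0, 6.0)]
    # eps well above the inner solver's objective noise so the numerical
    # gradient stays accurate
    res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12,
                            "eps": 1e-6})

    gamma = res.x[:2]
    s0, s1 = float(np.exp(res.x[2])), float(np.exp(res.x[3]))
    rho = float(np.tanh(res.x[4]))
    boundary = s0 < BOUNDARY_SIGMA or s1 < BOUNDARY_SIGMA
    if boundary:
        rho_out = 0.0 if min(s0, s1) < BOUNDARY_SIGMA else rho
    else:
        rho_out = rho
    Sigma = cov_matrix(s0, s1, rho)
    total, sol = laplace_marginal_loglik(z, y, offset, starts, gamma, Sigma,
                                         v_warm=warm["v"])
    ccov = conditional_covariances(sol["info"], Sigma)
    estimates = []
    cond_cov = {}
    for k, cid in enumerate(data.clusters_):
        estimates.append(CalibrationEstimate(
            cid, float(sol["v"][k, 0]), float(sol["v"][k, 1]),
            float(np.sqrt(max(ccov[k, 0, 0], 0.0))),
            float(np.sqrt(max(ccov[k, 1, 1], 0.0))),
            "random"))
        cond_cov[cid] = ccov[k]
    return MultilevelFit(
        gamma0=float(gamma[0]), gamma1=float(gamma[1]),
        sigma0=s0, sigma1=s1, rho=rho_out,
        estimates=estimates, cond_cov=cond_cov,
        loglik=float(total), converged=bool(res.success),
        n_iterations=int(res.nit), boundary=boundary,
        beta0=data.beta0, message=str(res.message), cov_re=Sigma,
    )


def fit_multilevel(data: ClusteredDataset, max_iter: int = 500,
                   gtol: float = 1e-6) -> MultilevelFit:
    """Laplace fit of the multilevel calibration model; see
    :class:`MultilevelCalibrator`."""
    return _multilevel_fit(data, max_iter=max_iter, gtol=gtol)
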