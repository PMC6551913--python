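"""Pairwise concordance measures for binary-outcome risk models.

Three related quantities live here:

* :func:`harrell_c` — the empirical concordance index (c-index), the
  probability that of two subjects with different outcomes the model
  assigns the higher risk to the subject with the event.  Identical to
  the area under the ROC curve for binary outcomes; ties in the
  predictions count one half.
* :func:`mbc` — the model-based concordance: the concordance probability
  *expected* under the model itself, i.e. assuming outcomes are Bernoulli
  draws from the predicted probabilities.  It is a function of the
  predictions alone and uses no observed outcomes.
* :func:`c_mbc` — the calibrated model-based concordance: the mbc of the
  predictions after recalibrating the linear predictor with a calibration
  intercept and slope, ``expit(gamma0 + gamma1 * logit)``.

All three are exact O(n log n) computations; brute-force O(n^2)
enumeration is only used in the test suite as an oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "ConcordanceUndefinedError",
    "harrell_c",
    "mbc",
    "expected_concordance",
    "c_mbc",
]


class ConcordanceUndefinedError(ValueError):
    """The c-index is undefined: outcomes contain only one class."""


def _as_prob_vector(probs, *, min_len: int = 2) -> np.ndarray:
    p = np.asarray(probs, dtype=float).ravel()
    if p.size < min_len:
        raise ValueError(f"need at least {min_len} subjects, got {p.size}")
    if not np.all(np.isfinite(p)):
        raise ValueError("predicted probabilities must be finite")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError(
            "predicted probabilities must lie strictly in (0, 1); "
            "refusing to clip — recompute the predictions instead"
        )
    return p


def harrell_c(probs, y) -> float:
    """Harrell's concordance index of predictions ``probs`` against binary ``y``.

    Over all pairs with discordant outcomes, counts 1 for a correctly
    ordered pair, 1/2 for a prediction tie, 0 otherwise.  Computed via the
    rank (Mann-Whitney) identity with midranks, which reproduces the
    pairwise count exactly, ties included.

    Raises
    ------
    ValueError
        If inputs are empty or lengths differ.
    ConcordanceUndefinedError
        If ``y`` is all zeros or all ones (no usable pairs).
    """
    p = np.asarray(probs, dtype=float).ravel()
    yv = np.asarray(y).ravel()
    if p.size == 0:
        raise ValueError("empty input")
    if p.size != yv.size:
        raise ValueError("probs and y must have the same length")
    if not np.isin(yv, (0, 1)).all():
        raise ValueError("y must be binary (0/1)")
    yv = yv.astype(int)
    n1 = int(yv.sum())
    n0 = yv.size - n1
    if n1 == 0 or n0 == 0:
        raise ConcordanceUndefinedError(
            "c-index undefined: outcomes are all "
            f"{'1' if n0 == 0 else '0'}"
        )
    # Midranks without scipy.stats.rankdata call overhead in hot loops.
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    ranks = np.empty(p.size, dtype=float)
    # average rank within tie groups
    boundaries = np.flatnonzero(np.diff(ps)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [p.size]))
    avg = (starts + ends - 1) / 2.0 + 1.0  # 1-based midranks
    ranks[order] = np.repeat(avg, ends - starts)
    u = ranks[yv == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def expected_concordance(scores, probs) -> float:
    """Expected c-index of a ranking ``scores`` under outcome probabilities ``probs``.

    Treats the outcomes as independent Bernoulli(``probs``) and the model
    ranking as ``scores``; returns N/D with, over unordered pairs (i, j),

    * D = sum of p_i (1 - p_j) + p_j (1 - p_i)
    * N = the same weights, keeping the term of the higher-scored subject,
      and half of both on a score tie.

    With ``scores = probs`` this is the model-based concordance.  The
    generalization matters when the ranking is correct but the outcome
    model generating the probabilities is not the ranking model itself.
    """
    s = np.asarray(scores, dtype=float).ravel()
    p = _as_prob_vector(probs)
    if s.size != p.size:
        raise ValueError("scores and probs must have the same length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n = p.size
    total = p.sum()
    # D = sum_{i<j} p_i + p_j - 2 p_i p_j  (independent of the ordering)
    denom = (n - 1) * total - (total * total - np.dot(p, p))
    order = np.argsort(s, kind="mergesort")
    ss = s[order]
    ps = p[order]
    # tie-group boundaries in the sorted scores
    boundaries = np.flatnonzero(np.diff(ss)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    grp_p = np.add.reduceat(ps, starts)            # sum of p per tie group
    grp_q = np.add.reduceat(1.0 - ps, starts)      # sum of (1-p) per group
    grp_pq = np.add.reduceat(ps * (1.0 - ps), starts)
    below_q = np.concatenate(([0.0], np.cumsum(grp_q)))[:-1]
    # concordant mass: higher-scored subject has the event
    num = float(np.dot(grp_p, below_q))
    # within-group ties contribute half their weight
    num += float(0.5 * np.sum(grp_p * grp_q - grp_pq))
    if denom <= 0.0:  # unreachable for probs in (0,1), kept as a guard
        raise ValueError("degenerate pair weights")
    return num / denom


def mbc(probs) -> float:
    """Model-based concordance of predicted probabilities.

    The concordance probability the model expects of itself: the mean
    c-index over infinitely many outcome vectors drawn from the model's
    own probabilities.  Always in [0.5, 1]; equal to 0.5 when all
    predictions are tied.  Not invariant under monotone transformations
    of the probabilities (unlike the c-index), because the pair weights
    p_i (1 - p_j) depend on the probabilities themselves.
    """
    p = _as_prob_vector(probs)
    return expected_concordance(p, p)


def c_mbc(logits, gamma0: float = 0.0, gamma1: float = 1.0) -> float:
    """Calibrated model-based concordance.

    Applies the recalibration ``expit(gamma0 + gamma1 * logits)`` and
    returns the mbc of the recalibrated predictions.  The logits must
    already include the original model intercept.  ``c_mbc(x, 0, 1)``
    equals ``mbc(expit(x))``; ``gamma1 = 0`` collapses all predictions
    and yields 0.5.
    """
    lv = np.asarray(logits, dtype=float).ravel()
    if lv.size < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(lv)):
        raise ValueError("logits must be finite")
    if not (np.isfinite(gamma0) and np.isfinite(gamma1)):
        raise ValueError("calibration coefficients must be finite")
    return mbc(expit(gamma0 + gamma1 * lv))
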