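"""Simulated clustered validation studies of a logistic prediction model.

The base study emulates external validation of an existing model in 40
clusters (centers) of 200 patients.  Heterogeneity across clusters is
placed on the calibration scale: each cluster k receives a true
calibration intercept ``g0k ~ N(0, 0.2^2)`` and slope
``g1k ~ N(1, 0.2^2)``, drawn once per experiment and held fixed across
replications.  Within a replication each patient gets a linear predictor
``z ~ N(0, casemix_sd_k^2)`` and a Bernoulli outcome with success
probability ``expit(-2 + g0k + g1k z)``; the average intercept of -2
gives a typical-cluster event rate of 15.5%.

Named preset scenarios vary one ingredient at a time:

==================  =====================================================
base                40 x 200, sigma0 = sigma1 = 0.2
no_heterogeneity    sigma0 = sigma1 = 0 (all clusters share (0, 1))
n400                400 patients per cluster
misspecified        outcomes generated from a dichotomized predictor,
                    expit(-0.5 + g0k + 2.75 g1k 1{z > 1}), while the
                    model still uses the continuous z
nonnormal_slopes    slopes shifted -0.2 in half the clusters, +0.2 in
                    the other half (bimodal, non-normal)
casemix_hetero      per-cluster SD of z drawn Uniform(0.75, 1.25)
reduced_slope       mean true slope 0.75 (weaker overall predictor)
==================  =====================================================

The per-cluster *true* concordance is the expected c-index of the model
ranking in infinitely many replications of that cluster, evaluated on a
large fresh case-mix sample.

Randomness is governed by one master seed: the truth draw and every
replication get independent, individually re-runnable child streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .cluster_metrics import cluster_discrimination
from .concordance import expected_concordance, mbc
from .data import ClusteredDataset
from .recalibration import fit_fixed_per_cluster, fit_multilevel

__all__ = [
    "ScenarioConfig",
    "TrueClusterParams",
    "PRESETS",
    "get_preset",
    "truth_rng",
    "replication_rng",
    "draw_cluster_truths",
    "generate_replication",
    "true_concordance",
    "run_experiment",
]

TRUTH_SAMPLE_SIZE = 200_000  # fresh z-sample size for the true concordance


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters of one simulation scenario."""

    K: int = 40                      # clusters
    n_k: int = 200                   # patients per cluster
    intercept: float = -2.0          # beta0 of the validated model
    gamma0_mean: float = 0.0         # mean true calibration intercept
    gamma1_mean: float = 1.0         # mean true calibration slope
    sigma0: float = 0.2              # between-cluster SD of intercepts
    sigma1: float = 0.2              # between-cluster SD of slopes
    slope_shift: float = 0.0         # -shift in first half of clusters, +shift in rest
    casemix_sd_range: tuple = (1.0, 1.0)  # Uniform range of per-cluster SD of z
    misspecified: bool = False       # dichotomized-predictor outcome generator
    replications: int = 2000
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        if self.K < 2 or self.n_k < 2:
            raise ValueError("need K >= 2 clusters and n_k >= 2 patients")
        if self.sigma0 < 0 or self.sigma1 < 0:
            raise ValueError("between-cluster SDs must be >= 0")
        lo, hi = self.casemix_sd_range
        if not (0 < lo <= hi):
            raise ValueError("casemix_sd_range must satisfy 0 < lo <= hi")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["casemix_sd_range"] = list(self.casemix_sd_range)
        return d


PRESETS = {
    "base": ScenarioConfig(name="base"),
    "no_heterogeneity": ScenarioConfig(sigma0=0.0, sigma1=0.0,
                                       name="no_heterogeneity"),
    "n400": ScenarioConfig(n_k=400, name="n400"),
    "misspecified": ScenarioConfig(misspecified=True, name="misspecified"),
    "nonnormal_slopes": ScenarioConfig(slope_shift=0.2, name="nonnormal_slopes"),
    "casemix_hetero": ScenarioConfig(casemix_sd_range=(0.75, 1.25),
                                     name="casemix_hetero"),
    "reduced_slope": ScenarioConfig(gamma1_mean=0.75, name="reduced_slope"),
}


def get_preset(name: str, **overrides) -> ScenarioConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset '{name}'; valid: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return cfg.replace(**overrides) if overrides else cfg


@dataclass
class TrueClusterParams:
    """One cluster's fixed truths, drawn once per experiment."""

    cluster_id: int
    gamma0_true: float
    gamma1_true: float
    casemix_sd: float
    true_concordance: float = np.nan


# --- seed lineage -----------------------------------------------------------
# master seed -> (truth stream) and (one stream per replication), all
# independently re-runnable.

def truth_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))


def replication_rng(seed: int, replication: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1, replication)))


def draw_cluster_truths(config: ScenarioConfig, rng: np.random.Generator):
    """Draw each cluster's true calibration intercept/slope and case-mix SD."""
    g0 = rng.normal(config.gamma0_mean, config.sigma0, config.K)
    g1 = rng.normal(config.gamma1_mean, config.sigma1, config.K)
    if config.slope_shift != 0.0:
        half = int(np.ceil(config.K / 2))
        g1[:half] -= config.slope_shift
        g1[half:] += config.slope_shift
    lo, hi = config.casemix_sd_range
    sd = np.full(config.K, lo) if lo == hi else rng.uniform(lo, hi, config.K)
    return [TrueClusterParams(k, float(g0[k]), float(g1[k]), float(sd[k]))
            for k in range(config.K)]


def _outcome_probs(z: np.ndarray, g0: float, g1: float,
                   config: ScenarioConfig) -> np.ndarray:
    if config.misspecified:
        return expit(-0.5 + g0 + 2.75 * g1 * (z > 1.0))
    return expit(config.intercept + g0 + g1 * z)


def generate_replication(truths, config: ScenarioConfig,
                         rng: np.random.Generator) -> ClusteredDataset:
    """One replicated validation dataset under the scenario's truths.

    The dataset always exposes the *continuous* ``z`` as the model's
    linear predictor; under the misspecified scenario only the outcome
    generator uses the dichotomized version.
    """
    if len(truths) != config.K:
        raise ValueError("truths do not match config.K")
    K, n = config.K, config.n_k
    cluster = np.repeat(np.arange(K), n)
    z = np.empty(K * n)
    p = np.empty(K * n)
    for t in truths:
        sl = slice(t.cluster_id * n, (t.cluster_id + 1) * n)
        zk = rng.normal(0.0, t.casemix_sd, n)
        z[sl] = zk
        p[sl] = _outcome_probs(zk, t.gamma0_true, t.gamma1_true, config)
    y = (rng.random(K * n) < p).astype(np.int8)
    return ClusteredDataset(cluster, z, y, beta0=config.intercept)


def true_concordance(truths, config: ScenarioConfig, rng: np.random.Generator,
                     n_large: int = TRUTH_SAMPLE_SIZE):
    """Fill in each cluster's true concordance probability (in place).

    Evaluates the expected c-index of the model's ranking on a fresh
    large case-mix sample: for the correctly specified generators this
    is ``mbc(beta0 + g0k + g1k * Z)``; for the misspecified generator
    the ranking is still the continuous ``z`` but the outcome
    probabilities come from the dichotomized true model, so the
    generalized expected concordance of (scores, true probs) is used.
    """
    if n_large < 10 ** 5:
        raise ValueError("n_large must be >= 1e5 for a stable truth")
    for t in truths:
        z = rng.normal(0.0, t.casemix_sd, n_large)
        p_true = _outcome_probs(z, t.gamma0_true, t.gamma1_true, config)
        if config.misspecified:
            t.true_concordance = expected_concordance(z, p_true)
        elif t.gamma1_true == 0.0:
            t.true_concordance = 0.5
        else:
            t.true_concordance = mbc(p_true)
    return truths


def truths_frame(truths) -> pd.DataFrame:
    return pd.DataFrame([{
        "cluster": t.cluster_id, "gamma0_true": t.gamma0_true,
        "gamma1_true": t.gamma1_true, "casemix_sd": t.casemix_sd,
        "true_concordance": t.true_concordance,
    } for t in truths])


def _replication_rows(rep: int, data: ClusteredDataset, config: ScenarioConfig):
    """Fit both estimators on one replication; tidy rows per cluster."""
    fixed = fit_fixed_per_cluster(data)
    mfit = fit_multilevel(data)
    discs = cluster_discrimination(data, mfit, n_draws=None)
    rows = []
    for fx, d in zip(fixed, discs):
        est = mfit.estimate_for(d.cluster_id)
        rows.append({
            "replication": rep, "cluster": d.cluster_id, "n": d.n,
            "n_events": d.n_events, "c_index": d.c_index, "c_mbc": d.c_mbc,
            "gamma0_fixed": fx.gamma0, "gamma1_fixed": fx.gamma1,
            "se0_fixed": fx.se0, "se1_fixed": fx.se1,
            "gamma0_random": est.gamma0, "gamma1_random": est.gamma1,
            "se0_random": est.se0, "se1_random": est.se1,
            "ml_converged": mfit.converged, "fixed_converged": fx.converged,
        })
    return rows, mfit.converged


def run_experiment(config: ScenarioConfig, output_dir=None, resume: bool = False,
                   n_large: int = TRUTH_SAMPLE_SIZE,
                   progress_every: Optional[int] = None, log=None):
    """Run one full replicated experiment.

    Draws the truths once, then loops replications of generate -> fixed
    fits -> multilevel fit -> per-cluster c-index and c-mbc.  When
    ``output_dir`` is given, truths and estimates stream to
    ``truths.csv`` / ``estimates.csv`` there (flushed every replication),
    and ``resume=True`` continues a partial run: because every
    replication has its own seed stream, finished replications are
    skipped and reproduced results are identical either way.

    Returns ``(truths_df, estimates_df, n_nonconverged)``.
    """
    import pathlib

    rng_t = truth_rng(config.seed)
    truths = draw_cluster_truths(config, rng_t)
    true_concordance(truths, config, rng_t, n_large=n_large)
    tdf = truths_frame(truths)

    est_path = truths_path = None
    done = set()
    existing = None
    if output_dir is not None:
        out = pathlib.Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        truths_path = out / "truths.csv"
        est_path = out / "estimates.csv"
        tdf.to_csv(truths_path, index=False, float_format="%.12g")
        if resume and est_path.exists():
            existing = pd.read_csv(est_path)
            done = set(existing["replication"].unique())
        elif est_path.exists():
            est_path.unlink()

    all_rows = [] if existing is None else [existing]
    n_bad = 0
    for rep in range(config.replications):
        if rep in done:
            continue
        rng_r = replication_rng(config.seed, rep)
        data = generate_replication(truths, config, rng_r)
        rows, converged = _replication_rows(rep, data, config)
        if not converged:
            n_bad += 1
        rep_df = pd.DataFrame(rows)
        all_rows.append(rep_df)
        if est_path is not None:
            rep_df.to_csv(est_path, mode="a", header=not est_path.exists(),
                          index=False, float_format="%.12g")
        if log is not None and progress_every and (rep + 1) % progress_every == 0:
            log(f"replication {rep + 1}/{config.replications} done "
                f"({n_bad} non-converged)")
    edf = pd.concat(all_rows, ignore_index=True).sort_values(
        ["replication", "cluster"], ignore_index=True)
    return tdf, edf, n_bad
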