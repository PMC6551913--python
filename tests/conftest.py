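import numpy as np
import pytest
from scipy.special import expit

from cmbc.data import ClusteredDataset
from cmbc.evaluation import summarize
from cmbc.simulation import get_preset, run_experiment


def simulate_clustered(seed, K=20, n=150, beta0=-2.0, sigma0=0.2, sigma1=0.2,
                       gamma0=0.0, gamma1=1.0):
    """Hand-rolled clustered generator for unit tests (independent of the
    package's simulation module)."""
    rng = np.random.default_rng(seed)
    g0 = rng.normal(gamma0, sigma0, K)
    g1 = rng.normal(gamma1, sigma1, K)
    cl = np.repeat(np.arange(K), n)
    z = rng.standard_normal(K * n)
    p = expit(beta0 + g0[cl] + g1[cl] * z)
    y = (rng.random(K * n) < p).astype(int)
    return ClusteredDataset(cl, z, y, beta0=beta0), g0, g1


@pytest.fixture(scope="session")
def base_experiment():
    """The replicated base-scenario experiment reused by the heavier
    acceptance checks: 40 clusters x 200 patients, one truth draw,
    500 replications."""
    cfg = get_preset("base", replications=500, seed=1)
    truths, estimates, n_bad = run_experiment(cfg)
    return {"config": cfg, "truths": truths, "estimates": estimates,
            "n_nonconverged": n_bad, "summary": summarize(estimates, truths)}


@pytest.fixture(scope="session")
def small_base_run():
    """A 5-replication base run for cheap structural checks."""
    cfg = get_preset("base", replications=5, seed=3)
    truths, estimates, n_bad = run_experiment(cfg)
    return {"config": cfg, "truths": truths, "estimates": estimates,
            "n_nonconverged": n_bad}
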