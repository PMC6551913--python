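import subprocess
import textwrap

import numpy as np
import pytest
from scipy.special import expit
from sklearn.base import clone

from cmbc.data import ClusteredDataset
from cmbc.recalibration import (
    FixedEffectsCalibrator,
    MultilevelCalibrator,
    fit_fixed_per_cluster,
    fit_multilevel,
)
from conftest import simulate_clustered
from oracles import glmm_loglik_quadrature


class TestFixedEffects:
    def test_matches_statsmodels_glm(self):
        """Per-cluster ML fits agree with statsmodels GLM with offset."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 400
        z = rng.standard_normal(n)
        y = (rng.random(n) < expit(-2 + 0.3 + 0.7 * z)).astype(int)
        data = ClusteredDataset(np.zeros(n), z, y, beta0=-2.0)
        # package needs >= 2 clusters for the dataset; duplicate the cluster
        data2 = ClusteredDataset(np.repeat([0, 1], n), np.tile(z, 2),
                                 np.tile(y, 2), beta0=-2.0)
        est = fit_fixed_per_cluster(data2)[0]
        X = sm.add_constant(z)
        ref = sm.GLM(y, X, family=sm.families.Binomial(),
                     offset=np.full(n, -2.0)).fit()
        assert est.gamma0 == pytest.approx(ref.params[0], abs=1e-6)
        assert est.gamma1 == pytest.approx(ref.params[1], abs=1e-6)
        assert est.se0 == pytest.approx(ref.bse[0], rel=1e-4)
        assert est.se1 == pytest.approx(ref.bse[1], rel=1e-4)

    def test_parameter_recovery_large_clusters(self):
        """logit(p) = beta0 + 0.5 + 0.8 z: the ML fits recover (0.5, 0.8),
        averaged over 10 clusters of n=2e4 to keep good statistical power."""
        rng = np.random.default_rng(10)
        K, n = 10, 20_000
        cl = np.repeat(np.arange(K), n)
        z = rng.standard_normal(K * n)
        y = (rng.random(K * n) < expit(-2 + 0.5 + 0.8 * z)).astype(int)
        ests = fit_fixed_per_cluster(ClusteredDataset(cl, z, y, beta0=-2.0))
        assert all(e.converged for e in ests)
        se0 = np.mean([e.se0 for e in ests]) / np.sqrt(K)
        se1 = np.mean([e.se1 for e in ests]) / np.sqrt(K)
        assert np.mean([e.gamma0 for e in ests]) == pytest.approx(
            0.5, abs=3 * se0)
        assert np.mean([e.gamma1 for e in ests]) == pytest.approx(
            0.8, abs=3 * se1)

    def test_self_calibrated_data(self):
        rng = np.random.default_rng(11)
        K, n = 8, 20_000
        cl = np.repeat(np.arange(K), n)
        z = rng.standard_normal(K * n)
        y = (rng.random(K * n) < expit(-2 + z)).astype(int)
        ests = fit_fixed_per_cluster(ClusteredDataset(cl, z, y, beta0=-2.0))
        for e in ests:  # each within 4 individual SEs
            assert abs(e.gamma0) < 4 * e.se0
            assert abs(e.gamma1 - 1.0) < 4 * e.se1
        assert abs(np.mean([e.gamma0 for e in ests])) < 0.03
        assert abs(np.mean([e.gamma1 for e in ests]) - 1.0) < 0.03

    def test_single_class_cluster_flagged_not_dropped(self):
        rng = np.random.default_rng(12)
        cl = np.repeat([0, 1], 50)
        z = rng.standard_normal(100)
        y = (rng.random(100) < expit(z)).astype(int)
        y[cl == 1] = 0  # degenerate cluster
        ests = fit_fixed_per_cluster(ClusteredDataset(cl, z, y, beta0=0.0))
        assert len(ests) == 2
        assert ests[0].converged
        assert not ests[1].converged
        assert np.isnan(ests[1].gamma1)
        assert "class" in ests[1].message or "separation" in ests[1].message

    def test_sklearn_api(self):
        data, _, _ = simulate_clustered(0, K=10, n=80)
        est = FixedEffectsCalibrator(beta0=-2.0)
        assert clone(est).get_params() == est.get_params()
        est.fit(data.to_frame()[["cluster", "lp"]], data.y)
        assert len(est.estimates_) == 10
        proba = est.predict_proba(data.to_frame()[["cluster", "lp"]])
        assert proba.shape == (data.n, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestMultilevel:
    def test_homogeneous_limit(self):
        """With no between-cluster heterogeneity the variance components
        collapse and the conditional modes agree across clusters."""
        rng = np.random.default_rng(13)
        K, n = 40, 200
        cl = np.repeat(np.arange(K), n)
        z = rng.standard_normal(K * n)
        y = (rng.random(K * n) < expit(-2 + z)).astype(int)
        fit = fit_multilevel(ClusteredDataset(cl, z, y, beta0=-2.0))
        # sigma-hat is noisy at K=40, n=200 (per-cluster slope SE ~ 0.25),
        # but must be well below the 0.2 of the heterogeneous scenario
        assert fit.sigma0 < 0.15 and fit.sigma1 < 0.15
        g0s = [e.gamma0 for e in fit.estimates]
        g1s = [e.gamma1 for e in fit.estimates]
        assert np.std(g0s) < 0.1 and np.std(g1s) < 0.1
        assert abs(np.mean(g0s) - fit.gamma0) < 0.05
        assert abs(np.mean(g1s) - fit.gamma1) < 0.05

    def test_shrinkage_vs_fixed(self):
        data, _, _ = simulate_clustered(14, K=25, n=150)
        fit = fit_multilevel(data)
        fixed = fit_fixed_per_cluster(data)
        ok = [i for i, e in enumerate(fixed) if e.converged]
        f0 = np.array([fixed[i].gamma0 for i in ok])
        f1 = np.array([fixed[i].gamma1 for i in ok])
        r0 = np.array([fit.estimates[i].gamma0 for i in ok])
        r1 = np.array([fit.estimates[i].gamma1 for i in ok])
        assert np.std(r0) <= np.std(f0)
        assert np.std(r1) <= np.std(f1)
        # conditional SEs are narrower than ML SEs (shrunken intervals)
        assert np.mean([fit.estimates[i].se1 for i in ok]) < np.mean(
            [fixed[i].se1 for i in ok])

    def test_conditional_modes_maximize_joint_density(self):
        """At the returned modes, the gradient of each cluster's penalized
        log-likelihood (given the population parameters) vanishes."""
        data, _, _ = simulate_clustered(15, K=12, n=100)
        fit = fit_multilevel(data)
        prec = np.linalg.inv(fit.cov_re + 1e-12 * np.eye(2))
        gamma = np.array([fit.gamma0, fit.gamma1])
        codes, z, y, starts = data.sorted_by_cluster()
        ends = np.append(starts[1:], len(z))
        for k, cid in enumerate(data.clusters_):
            e = fit.estimate_for(cid)
            v = np.array([e.gamma0, e.gamma1])
            zk, yk = z[starts[k]:ends[k]], y[starts[k]:ends[k]]
            p = expit(data.beta0 + v[0] + v[1] * zk)
            grad = np.array([(yk - p).sum(), ((yk - p) * zk).sum()])
            grad -= prec @ (v - gamma)
            assert np.abs(grad).max() < 1e-4

    def test_laplace_objective_against_quadrature(self):
        """On a 2-cluster toy the Laplace marginal log-likelihood matches
        brute-force 2-D quadrature within 1% relative error."""
        from cmbc._glm import cov_matrix, laplace_marginal_loglik

        rng = np.random.default_rng(16)
        K, n = 2, 120
        g0 = np.array([0.2, -0.3])
        g1 = np.array([1.3, 0.8])
        zs, ys = [], []
        for k in range(K):
            z = rng.standard_normal(n)
            y = (rng.random(n) < expit(-1 + g0[k] + g1[k] * z)).astype(int)
            zs.append(z)
            ys.append(y)
        gamma = np.array([0.0, 1.0])
        for s0, s1, rho in [(0.3, 0.3, 0.0), (0.5, 0.2, -0.4), (0.15, 0.4, 0.6)]:
            Sigma = cov_matrix(s0, s1, rho)
            zz = np.concatenate(zs)
            yy = np.concatenate(ys)
            starts = np.array([0, n])
            lap, _ = laplace_marginal_loglik(zz, yy, np.full(2 * n, -1.0),
                                             starts, gamma, Sigma)
            quad = glmm_loglik_quadrature(zs, ys, -1.0, gamma, Sigma)
            assert lap == pytest.approx(quad, rel=0.01)

    def test_against_lme4(self, tmp_path):
        """Population estimates agree with lme4::glmer (Laplace) on a
        moderately heterogeneous dataset."""
        data, _, _ = simulate_clustered(17, K=20, n=150, sigma0=0.5, sigma1=0.4)
        fit = fit_multilevel(data)
        csv = tmp_path / "d.csv"
        data.to_frame().to_csv(csv, index=False)
        rout = tmp_path / "out.txt"
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ lp + (1 + lp | cluster), data=d, family=binomial,
                       offset=rep({data.beta0}, nrow(d)))
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            cat(fe[1], fe[2], vc$sdcor[1], vc$sdcor[2],
                as.numeric(logLik(m)), sep="\\n",
                file="{rout}")
        """)
        subprocess.run(["Rscript", "-e", script], check=True, timeout=300,
                       capture_output=True)
        g0_r, g1_r, s0_r, s1_r, ll_r = map(float, rout.read_text().split())
        assert fit.gamma0 == pytest.approx(g0_r, abs=0.02)
        assert fit.gamma1 == pytest.approx(g1_r, abs=0.02)
        assert fit.sigma0 == pytest.approx(s0_r, abs=0.05)
        assert fit.sigma1 == pytest.approx(s1_r, abs=0.05)
        # same objective (both Laplace): neither optimum clearly worse
        assert fit.loglik >= ll_r - 0.5

    def test_few_clusters_warns_but_fits(self):
        data, _, _ = simulate_clustered(18, K=5, n=100)
        with pytest.warns(UserWarning, match="clusters"):
            fit = fit_multilevel(data)
        assert np.isfinite(fit.loglik)
        assert len(fit.estimates) == 5

    def test_sklearn_api(self):
        data, _, _ = simulate_clustered(19, K=12, n=100)
        est = MultilevelCalibrator(beta0=-2.0)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        est.fit(data.to_frame()[["cluster", "lp"]], data.y)
        for attr in ("gamma0_", "gamma1_", "sigma0_", "sigma1_", "rho_",
                     "loglik_", "converged_", "n_iter_"):
            assert hasattr(est, attr)
        assert -1.0 <= est.rho_ <= 1.0
        assert est.sigma0_ >= 0 and est.sigma1_ >= 0
        proba = est.predict_proba(data.to_frame()[["cluster", "lp"]])
        assert np.all((proba > 0) & (proba < 1))
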