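# cmbc — calibrated model-based concordance for clustered validation data

Validating a clinical prediction model in multicenter data raises an
awkward question: how well does the model discriminate *within each
center*?  The center-specific concordance index (c-index) — the
probability that of two patients with different outcomes the model
assigns the higher risk to the one with the event — is unbiased but
wildly unstable when centers hold only a couple of hundred patients and
a few dozen events.

`cmbc` implements a shrinkage alternative.  For a logistic model with
linear predictor z (log-odds, excluding the model intercept β₀), it
fits the multilevel recalibration model

    logit(p_ik) = offset(β0) + γ0k + γ1k · z_ik,
    (γ0k, γ1k) ~ N((γ0, γ1), Σ),   Σ = [[σ0², ρσ0σ1], [ρσ0σ1, σ1²]]

by Laplace-approximated maximum likelihood, giving each cluster a
*shrunken* calibration intercept γ̂0k and slope γ̂1k (conditional modes,
the logistic analogue of BLUPs).  Plugging these into the model-based
concordance — the concordance the model expects of itself,

    mbc(p) = Σ_{i<j} [ p_i(1−p_j)·1(p_i>p_j) + p_j(1−p_i)·1(p_j>p_i)
                       + ½(p_i(1−p_j)+p_j(1−p_i))·1(p_i=p_j) ]
             / Σ_{i<j} [ p_i(1−p_j) + p_j(1−p_i) ]

— yields the **calibrated model-based concordance** of cluster k:

    c-mbc_k = mbc( expit( β0 + γ̂0k + γ̂1k · Z_k ) ).

The c-mbc uses no observed outcomes once the calibration is estimated
(it even exists for clusters without events), inherits the stability of
the shrunken calibration estimates, and trades a small bias toward the
average cluster for a large variance reduction: in the package's
replicated base simulation (40 clusters × 200 patients, between-cluster
calibration SDs of 0.2) its root mean squared error is roughly 0.028
against 0.047–0.050 for the naive c-index.

## Worked example

```python
import numpy as np
from scipy.special import expit
from cmbc import ClusteredDataset, fit_multilevel, cluster_discrimination, pooled_cmbc

# external validation of a model with intercept beta0 = -2 in 12 centers
rng = np.random.default_rng(7)
K, n = 12, 150
g0, g1 = rng.normal(0.0, 0.3, K), rng.normal(0.9, 0.2, K)
center = np.repeat(np.arange(K), n)
lp = rng.standard_normal(K * n)            # linear predictors (no intercept)
y = rng.random(K * n) < expit(-2 + g0[center] + g1[center] * lp)

data = ClusteredDataset(center, lp, y.astype(int), beta0=-2.0)
fit = fit_multilevel(data)
print(f"population calibration: gamma0={fit.gamma0:.2f}, gamma1={fit.gamma1:.2f}")
print(f"between-center SDs: sigma0={fit.sigma0:.2f}, sigma1={fit.sigma1:.2f}, rho={fit.rho:.2f}")
print(f"pooled c-mbc: {pooled_cmbc(data, fit):.3f}")
for d in cluster_discrimination(data, fit, n_draws=2000, seed=1)[:3]:
    print(f"center {d.cluster_id}: n={d.n}, events={d.n_events}, "
          f"c-index={d.c_index:.3f} [{d.c_index_lo:.3f}, {d.c_index_hi:.3f}], "
          f"c-mbc={d.c_mbc:.3f} [{d.c_mbc_lo:.3f}, {d.c_mbc_hi:.3f}]")
```

prints

```
population calibration: gamma0=-0.05, gamma1=0.74
between-center SDs: sigma0=0.09, sigma1=0.25, rho=0.08
pooled c-mbc: 0.692
center 0: n=150, events=16, c-index=0.756 [0.613, 0.898], c-mbc=0.689 [0.608, 0.761]
center 1: n=150, events=24, c-index=0.624 [0.495, 0.752], c-mbc=0.664 [0.579, 0.735]
center 2: n=150, events=22, c-index=0.716 [0.589, 0.844], c-mbc=0.708 [0.625, 0.780]
```

The population slope of 0.74 says the model is overfitted on average in
this validation sample; center-level c-indexes swing from 0.62 to 0.76
with intervals spanning ±0.13, while the c-mbc estimates sit closer
together with roughly half the interval width — that is the shrinkage
the method is designed for.  Sampling noise alone moves naive per-center
estimates this much at n = 150; the c-mbc reads through it.

The same analysis is available from the shell for a CSV with
`cluster, lp, y` columns:

```bash
cmbc validate data.csv --beta0 -2 --out report/ --min-events 10
cmbc simulate base --reps 500 --seed 1 --out runs/base/
cmbc plot runs/base/
```

`validate` writes the per-cluster table (`clusters.csv`), pooled
estimates (`pooled.json`), a three-panel forest plot and a manifest;
`simulate` runs a replicated scenario experiment (presets: `base`,
`no_heterogeneity`, `n400`, `misspecified`, `nonnormal_slopes`,
`casemix_hetero`, `reduced_slope`) and summarizes per-cluster bias, SD
and rmse of both estimators against the simulated truths.

The estimators also come in scikit-learn form
(`FixedEffectsCalibrator`, `MultilevelCalibrator` with
`fit`/`predict_proba`/`get_params`), so they compose with sklearn
pipelines and model selection.

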