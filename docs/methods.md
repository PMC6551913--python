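# Methods

## The measures

**c-index.** For binary outcomes, Harrell's concordance index over all
pairs with discordant outcomes, counting 1 for a correctly ordered pair
and ½ for a prediction tie.  Computed through the Mann-Whitney midrank
identity, which reproduces the pairwise count exactly (ties included) in
O(n log n).

**mbc (model-based concordance).** The concordance probability a model
expects of itself if outcomes really are Bernoulli draws from its
predicted probabilities p: over unordered pairs (i, j), the probability
that exactly one of the pair has the event and it is the higher-ranked
one, plus half the tied mass, divided by the probability that exactly
one has the event.  It uses no observed outcomes, lies in [0.5, 1], and
equals the mean c-index over infinitely many outcome vectors simulated
from p — the defining property, verified against Monte-Carlo simulation
in the tests.  Unlike the c-index it is *not* invariant under monotone
transformations of p, because the pair weights p_i(1−p_j) live on the
probability scale.

A deliberate convention: the package sums over unordered *distinct*
pairs.  An alternative convention that also counts self-pairs would make
the mbc exactly equal to the c-index for a model with a single
categorical predictor, but it breaks the mean-c-index property at small
n (for p = (0.9, 0.1) it gives 0.900 where the mean simulated c-index is
0.81/0.82 ≈ 0.98780).  We keep the distinct-pairs form; the
single-binary-predictor equality then holds to O(1/n), which the tests
assert as convergence.

The generalized form `expected_concordance(scores, probs)` decouples
the ranking from the outcome model; it is used to define the true
concordance under the misspecified simulation scenario (below).

**c-mbc.** The mbc of recalibrated predictions
expit(γ0 + γ1·logit): calibrated model-based concordance.  With
cluster-specific (γ̂0k, γ̂1k) from the multilevel model, this is the
per-cluster discrimination estimate the package exists for.

## The multilevel recalibration model

Per cluster k: logit(p_ik) = offset(β0) + γ0k + γ1k z_ik with
(γ0k, γ1k) bivariate normal around population means (γ0, γ1) with SDs
(σ0, σ1) and correlation ρ.  β0 is the validated model's intercept and
is never refitted.

Fitting is nested maximum likelihood under the Laplace approximation,
the same order of approximation as lme4's default for binary GLMMs:

* **Inner:** for fixed parameters, each cluster's conditional mode
  maximizes its penalized log-likelihood.  All clusters are solved
  simultaneously by damped Newton on `np.add.reduceat` group sums (the
  per-cluster problem is 2-dimensional and concave); the stopping rule
  is the scale-invariant Newton decrement < 1e-13.
* **Outer:** L-BFGS-B over (γ0, γ1, log σ0, log σ1, atanh ρ), so the
  variance search is unconstrained; gradient tolerance 1e-6, at most
  500 iterations, deterministic initialization from the pooled fixed
  fit with (σ0, σ1, ρ) = (0.1, 0.1, 0).  The finite-difference step is
  1e-6, chosen well above the inner solver's objective noise — with the
  default 1e-8 step the numerical gradient is noise-dominated and the
  optimizer stalls visibly short of the optimum.
* The per-cluster Laplace correction is computed as
  −½ log det(I + Σ A_k) with A_k the logistic observed information at
  the mode, a form that stays finite at the σ → 0 boundary.  A fitted
  SD below 1e-4 is reported as a boundary fit (a valid outcome, and the
  reported ρ is zeroed when a variance collapses, since it is then
  unidentified).

On test data the implementation agrees with lme4::glmer (fixed effects
and variance components to ~3 decimals, log-likelihood to 4) and with
brute-force 2-D quadrature of the marginal likelihood within 1%.
Conditional covariances are (A_k + Σ⁻¹)⁻¹, computed as (I + ΣA_k)⁻¹Σ;
conditional-mode intervals are mode ± 1.96 conditional SD.

**Fixed-effect comparator.** Independent per-cluster ML logistic fits
(same Newton machinery, no penalty).  Separation or a single-class
cluster is flagged with NaN coefficients and a diagnostic message, never
silently dropped; such clusters still contribute to the multilevel
likelihood.

## Intervals

* c-index: Hanley–McNeil asymptotic SE, ±1.96 SE, clipped to [0, 1].
  Any standard choice would do; this one is deterministic and cheap.
* c-mbc: Monte Carlo through the conditional distribution — draw
  (γ0k, γ1k) from N(mode, conditional covariance), map through the
  c-mbc, take 2.5/97.5 percentiles (default 2000 draws, fixed seed).
  This respects the [0.5, 1] boundary where a delta method would not.
  Only conditional (cluster-level) uncertainty is propagated; the
  uncertainty of the population parameters (γ0, γ1, Σ) is not, so the
  intervals are somewhat anti-conservative — a known limitation.

## The simulation study

The generator emulates external validation of a logistic model in K
clusters: truths (γ0k, γ1k) are drawn *once per experiment* from
N(0, σ0²) × N(1, σ1²) and held fixed across replications; per
replication, z_ik ~ N(0, casemix_sd_k²) and
y_ik ~ Bernoulli(expit(−2 + γ0k + γ1k z_ik)).  With intercept −2 a
typical cluster has a 15.5% event rate.  Defaults: K = 40, n_k = 200,
σ0 = σ1 = 0.2, 2000 replications (the replicated acceptance runs use
500, which already pins the average-row summaries to well within ±0.01).

Scenario presets vary one ingredient at a time: no heterogeneity
(σ = 0), n_k = 400, a misspecified generator (outcomes driven by the
dichotomized predictor, expit(−0.5 + γ0k + 2.75 γ1k·1{z > 1}), while
the model still sees continuous z), bimodal slopes (±0.2 shifts in
either half of the clusters, assigned by cluster id — any fixed
assignment is equivalent by symmetry), case-mix heterogeneity
(casemix_sd ~ U(0.75, 1.25)) and a reduced mean slope of 0.75.

**True concordance.** Each cluster's truth is the expected c-index of
the model's ranking in infinitely many replications, evaluated on a
fresh z-sample of 2×10⁵ — the stable limit of the definition rather
than any single replication's realized case mix.  For the correctly
specified scenarios this is mbc(−2 + γ0k + γ1k Z); under the
misspecified generator the package evaluates the generalized expected
concordance of the continuous ranking against the dichotomized true
outcome probabilities, which is what the c-index is actually estimating
there.

**Seed lineage.** One master seed spawns a truth stream and one stream
per replication (`SeedSequence(seed, spawn_key=(1, r))`), so any single
replication can be reproduced in isolation and interrupted runs can be
resumed bitwise-identically.

**Summaries.** Per cluster and estimator: bias = mean(est − truth),
SD with the R−1 denominator, rmse with the R denominator, so
rmse² = bias² + sd²(R−1)/R holds exactly and is asserted in tests.
Clusters are reported sorted by true concordance with an unweighted
average row; replications with an undefined c-index are excluded
pairwise for that cluster with the count reported.  Report tables round
to 3 decimals.

## What the simulations do and do not show

The generator reproduces the mechanism the method targets —
heterogeneous calibration across small clusters — but simulates the
linear predictor directly: there is no covariate structure, no
within-cluster correlation beyond calibration, no missing data, and
cluster sizes are balanced.  Passing tests therefore demonstrate the
estimator's bias–variance behavior under the stated mechanism, not
performance on any particular clinical dataset.  Real validation data
enter through the `validate` workflow, which makes no balance
assumptions (unequal cluster sizes are handled throughout).

## Known limitations

* Laplace (not adaptive Gauss–Hermite) likelihood; variance components
  for binary outcomes carry the usual small downward bias, ~0.005 at
  the base design in the recovery tests.
* c-mbc intervals omit population-parameter uncertainty (above).
* The c-mbc is deliberately biased toward the average cluster; in
  clusters whose true concordance is far from the average, its bias can
  exceed the c-index's (the rmse advantage held in every simulated
  scenario, but per-cluster bias grows with |truth − average|).
* Fewer than ~10 clusters leaves the between-cluster variances poorly
  identified; the fit proceeds with a warning.
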