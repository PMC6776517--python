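# Methods

## Model and assumptions

The likelihood is a log-linear Poisson model for stratified areal counts.
Each area contributes four strata (two age groups × two sexes); the offset
`E_ikl` converts the linear predictor into a relative risk, so `exp(alpha)`
is the baseline risk of the reference stratum (age ≤60, female) relative to
the standard rate, and each `exp(beta)` is a relative risk per unit of its
covariate. Age is dichotomised at 60 years with 60 itself in the lower
group. The convolution decomposition follows the Besag–York–Mollié
tradition: an exchangeable normal term `u_i` absorbs area-level
overdispersion with no spatial pattern, and an intrinsic CAR term `s_i`
absorbs spatially smooth variation, defined only up to an additive constant
and therefore constrained to sum to zero. The zero-inflated variant treats
excess zeros at the *area* level: a structurally-zero area has all four of
its strata silenced. Stratum-level inflation would be an alternative
reading; area-level is the conventional one for areal ZIP models and is the
package's documented choice.

Two offset conventions are supported and must be chosen explicitly:

* **cohort** (default for modelling): `E_ikl = N_ikl · (ΣO/ΣN)` where `N`
  is the screened-cohort denominator of the same table. The regression's
  denominator is then exactly the population at risk in the data.
* **population** (for SMR maps): `E_i = pop_i · (ΣO/Σpop)` from an external
  per-area population, apportioned to strata by participant share.

Both satisfy the indirect-standardization identity `ΣE = ΣO` exactly, so
the SMRs average to 1 weighted by expectation.

## Priors and defaults

| parameter | prior | default hyperparameters |
|---|---|---|
| intercept `alpha` | flat | — |
| coefficients `beta` | normal | mean 0, precision 1e-4 (sd 100) |
| `1/sigma2_u`, `1/sigma2_s` | gamma | shape = rate = 0.001 |
| ZIP weight `pi0` | beta | (1, 1) |

The gamma rate for the structured precision uses the ICAR kernel
`tau_s^(rank(Q)/2) · exp(-tau_s/2 · Σ_edges (s_i - s_j)^2)` with
`rank(Q) = (#non-island areas) − (#multi-area components)`; the sum runs
over unordered neighbour pairs, each counted once.

## Sampler

Metropolis-within-Gibbs. The Poisson likelihood breaks conjugacy for
`alpha`, `beta`, `u` and `s`, which get Gaussian random-walk Metropolis
steps; the precisions and the ZIP indicators/weight have exact conjugate
Gibbs draws. Design choices that matter:

* **Vectorised single-site updates.** All `u_i` are conditionally
  independent and updated simultaneously. The `s_i` are updated
  simultaneously *within colour classes* of the adjacency graph (greedy
  colouring; no two areas in a class are neighbours), which preserves the
  single-site ICAR full conditionals while keeping each sweep a handful of
  array operations. Likelihood deltas use cached per-stratum means, and the
  cache is recomputed exactly once per sweep to stop floating-point drift;
  the fast-path arithmetic is pinned to a full-recompute reference
  implementation in the test suite (identical seeds must give identical
  trajectories).
* **Sum-to-zero by an invariant move.** After each `s` sweep the shift
  `(alpha, s) -> (alpha + mean(s), s - mean(s))` is applied. Under the flat
  intercept prior and the shift-invariant ICAR kernel this leaves the
  posterior density unchanged, so the chain remains exact while `s` stays
  identified. Isolated areas (no neighbours) have `s_i` pinned at 0 and are
  excluded from the constraint; because the shift then changes their
  likelihood, it is applied as a Metropolis move with the islands'
  likelihood ratio as acceptance probability (always accepted when there
  are no islands).
* **Adaptation during burn-in only.** Each proposal scale is nudged by
  `exp(0.5·(acc − 0.3))` toward the 0.2–0.4 acceptance band and frozen at
  the end of burn-in, so the retained chain is a fixed Markov kernel.
* **Overdispersed starts.** `alpha` starts at the pooled `log(ΣO/ΣE)` plus
  N(0, 0.5) jitter, coefficients and random effects at jittered zeros,
  variances at 1 — dispersed starts are what make the Gelman–Rubin
  diagnostic meaningful.
* **Batched stopping rule.** After a burn-in (default 10,000 sweeps),
  batches of 15,000 sweeps are retained until the PSRF of every scalar
  parameter (intercept, coefficients, variances, deviance) drops below 1.1,
  up to 3 batches; otherwise the output is returned flagged non-converged,
  never silently. Per-area random effects get PSRFs in the diagnostics
  report but do not drive the stopping decision, since thousands of weakly
  identified effects would make the rule needlessly conservative.
* **Prior-only mode** switches the likelihood off so every kernel's
  stationary marginal can be checked against its prior; the intercept is
  pinned in that mode because a flat prior has no marginal to sample.

DIC uses the recorded deviance: `Dbar` is its posterior mean and
`D_at_mean` evaluates the deviance at the posterior mean of the *full*
parameter vector, random effects included (the convention of the classic
Bayesian disease-mapping software), giving `pD = Dbar − D_at_mean` and
`DIC = Dbar + pD`. For the ZIP family the deviance is the observed-data
mixture likelihood with the indicators integrated out.

RR summaries are posterior means and equal-tailed quantiles of the
*exponentiated* draws. By Jensen's inequality the RR posterior mean is
never below `exp` of the coefficient posterior mean; reported RRs therefore
sit slightly above the naive transform, which is expected behaviour rather
than an inconsistency.

## Synthetic data

The generator emulates a large rare-outcome screening cohort at desk scale.
Defaults, fixed once: a 10×10 rook-contiguity lattice (100 areas, 400
strata); per-stratum denominators uniform on [50, 200] (≈50,000 participants
per dataset); baseline case fraction 0.0036; age and sex log relative risks
(1.08, 0.93); `sigma2_u = 0.25` and `sigma2_s = 1.0` as moderate
heterogeneity with spatial dominance; no zero inflation unless requested.
Counts are Poisson draws truncated at the stratum denominator by resampling
— at these rates truncation is an exceedingly rare event, so the Poisson
likelihood used in estimation remains essentially exact. The ICAR field is
drawn exactly by spectral decomposition of the graph Laplacian, dropping
null eigenvectors (equivalent to per-component sum-to-zero centring); a
dense pseudo-inverse covariance oracle backs this in tests. Continuous
covariates are iid standard normal per area.

What the generator does **not** emulate: raster-derived covariate fields
with their own spatial autocorrelation, irregular polygon geometries and
neighbour-count distributions, population size gradients, age structure
beyond the two-group split, and data-quality artefacts (duplicate records,
geocoding error). Passing tests therefore demonstrate correctness of the
algorithms under the assumed model, not robustness to real registry
messiness.

## Numerical choices

* Reported percentages round half-up to 2 decimals (what printed cohort
  tables use); confidence intervals for percentages are Wald intervals.
* Contiguity from polygons: queen (any boundary contact) is the default,
  rook (shared segment of positive length) a flag; contact tolerance 1e-9
  in coordinate units for digitisation noise. Lattice graphs are rook.
* `SMR = O/E` with `E = 0` yields NaN when `O = 0` (undefined) and +inf
  with a flag when `O > 0`.
* Strata with non-positive expected counts are dropped from the model
  design (logged); they carry no likelihood information.
* The GLM screen uses IRLS (statsmodels) with Wald tests and
  `BIC = −2ℓ + p·log n`; a constant covariate is flagged inestimable rather
  than fitted; collinearity above |r| = 0.8 is reported, not enforced.
* Desk-scale schedule used throughout the tests and the acceptance script:
  2 chains, 2,000 burn-in, batches of 5,000 retained draws — roughly a
  third of the full defaults in each dimension, chosen as the smallest
  schedule at which the scalar PSRFs reliably clear 1.1 on the default
  synthetic conditions.

## Known limitations

* The two variance components of the convolution model are only weakly
  identified (a classic BYM property); `sigma2_u`/`sigma2_s` mix an order
  of magnitude slower than the coefficients, and short runs can flag
  non-convergence on the variances while the coefficient posteriors are
  already stable.
* The ICAR prior is improper; only contrasts of `s` and the sum
  `alpha + s_i` are identified. With several graph components the global
  sum-to-zero constraint (matching the classic software's behaviour) still
  leaves per-component levels to be soaked up by `u`, which slightly
  inflates `sigma2_u` on disconnected maps.
* Proper CAR models, spatiotemporal structure, HMC/slice samplers and WAIC
  are out of scope; DIC is reported because it is the established selector
  in this workflow, despite its known weaknesses for mixture likelihoods.
* The ZIP deviance integrates the indicators out, so ZIP and Poisson DICs
  are comparable, but pD for strongly inflated data should be interpreted
  with care.
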