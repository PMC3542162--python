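# Methods

This note records the statistical model, estimation choices, simulation
design and known limitations of `remr`. It is the package's own account of
what it computes and why; every number mentioned here is produced by the test
suite or by `scripts/acceptance.py`.

## Subject-level mixed models

**Linear mixed model (continuous outcome).** For subject *i* with n_i visits,
Y_i = X_i β + Z_i b_i + e_i, b_i ~ N(0, G), e_i ~ N(0, σ²I), giving the
marginal likelihood with Σ_i = Z_i G Z_i′ + σ²I. The random structure is a
subject intercept (q = 1) or intercept + linear time slope (q = 2). The
objective (ML or REML; REML is the default, matching common practice for
variance components) is profiled twice: β has its GLS closed form, and σ² has
a closed-form update once the covariance is written σ²Λ_i(Γ) with
Γ = G/σ². What remains is a 1-parameter (q=1) or 3-parameter (q=2) search:

* q = 1: bounded Brent search on log Γ over [−16, 23] (xatol 1e-10). The
  unconstrained scale cannot represent Γ = 0 exactly, so the boundary is
  checked explicitly and variance estimates below 1e-8 are reported as exact
  zeros with a `boundary` flag.
* q = 2: L-BFGS-B on the log-Cholesky parameters of Γ (diagonal on log
  scale), which keeps every iterate positive semidefinite.

All per-subject quantities are accumulated with `numpy.add.reduceat` and the
Woodbury identity, so one objective evaluation is O(rows); a 200-subject,
5-visit REML fit takes ~10 ms and the partition-and-pool pipeline over 20
clusters runs in well under a second.

**Logistic mixed model (binary outcome).** Random intercept only. The
marginal likelihood integrates the Bernoulli likelihood over b_i ~ N(0,
σ_b²); the integral is approximated by adaptive Gauss–Hermite quadrature
(default 15 nodes) centered and scaled at each subject's posterior mode,
found by a vectorized Newton iteration. The parameters (β, log σ_b) are
maximized by BFGS on the mean log-likelihood (gradient by finite
differences; gradient tolerance 1e-7, max 300 iterations), started from the
plain logistic MLE. Standard errors come from the observed information
computed by central finite differences of the objective. Apparent separation
(|β| diverging past 30) is reported as a warning with `converged=False`,
never silently.

A dense-trapezoid grid integrator over ±8 SD of the random intercept (4001
points, ≤ 50 subjects by contract) serves as the independent oracle for the
quadrature; agreement is below 1e-6 in absolute log-likelihood at ≥ 15 nodes
on the test datasets, and the error decreases monotonically in the node
count.

**Weighted pseudo-likelihood.** Sampling weights are per-subject (constant
across a subject's visits, strictly positive) and multiply the subject's
marginal log-likelihood contribution as frequency-style multipliers. An
integer weight w is therefore *exactly* equivalent to replicating the subject
w times, which is the property the unit tests assert. By default weights are
rescaled to sum to the number of analyzed subjects; this rescaling multiplies
the whole ML objective by a constant (point estimates unchanged) but is not
exactly neutral for the REML-form gaussian pseudo-likelihood, where the
profiling denominator n_w − p breaks scale invariance at order p/n — the
replication-equivalence test therefore runs in raw-weight mode
(`normalize_weights=False`). With `robust_se`, the reported covariance is the
subject-level sandwich: bread = inverse observed information, meat = outer
products of per-subject weighted scores (scores obtained by central
differences of the vectorized per-subject log-likelihoods).

**Information criteria.** AIC = −2ℓ + 2k, BIC = −2ℓ + k·log m, where k counts
fixed effects plus distinct variance components and m is the number of
subjects — the independent units of the marginal likelihood. Criteria from
pseudo-likelihood fits carry `ic_comparable=False`: pseudo-criteria are not
comparable across different pseudo-data, and pooled per-cluster criteria are
not comparable with full-data ones (the pooled report is flagged the same
way).

## Pooling by meta-regression

Each coefficient is pooled separately, with its own between-cluster variance
(a multivariate joint pooling is out of scope). The fixed-effects fit is
inverse-variance weighted least squares of φ_i on an intercept plus optional
cluster-level covariates z_i and cluster aggregates x_i. Cochran's
Q is the weighted residual sum of squares from that fit, with df = k − 1 −
(number of meta-covariates); I² = max(0, (Q−df)/Q).

The random-effects fit estimates σ_v² by the one-step DerSimonian–Laird
moment estimator σ̂_v² = max(0, (Q − df)/tr(P)) — where tr(P) reduces to
Σw − Σw²/Σw for the intercept-only case — then re-weights with
w*_i = 1/(σ_i² + σ̂_v²). The 95% interval uses normal quantiles (the classic
one-step form); a Knapp–Hartung adjustment is available behind a flag but is
not the default. The REML alternative maximizes the restricted likelihood by
bounded 1-D search over σ_v² with (τ, γ) profiled (tolerance 1e-10); it
matches R's `metafor::rma(method="REML")` to 1e-8 on the test fixture.

**Outlier screening.** The screen iterates: for each cluster compute the
externally standardized residual (φ_i − τ₍₋ᵢ₎)/√(σ_i² + σ̂²_{v,(−i)} +
se²(τ₍₋ᵢ₎)) from a DerSimonian–Laird fit on the other clusters; exclude the
largest absolute residual exceeding the threshold (default 3.0); repeat,
never dropping below 3 kept clusters, with ties broken by cluster-id order.
The leave-one-out operationalization and the 3.0 default are this package's
choices — no numeric rule is standard — and exclusions are always reported.
A design-time power analysis of the opposite-direction-pair scenario (two
clusters shifted ±6 cluster-SEs) showed that each outlier dilutes the
other's residual through the inflated leave-one-out σ̂_v², so exact recovery
of the pair needs a panel of roughly 15+ clean clusters to exceed 95%; with
10 clean clusters the exact-recovery rate is ≈ 91–92%. The acceptance test
therefore uses a 23-cluster panel (21 clean + the injected pair), the size of
the motivating application.

**Cluster-wise fitting.** Clusters are fitted independently in sorted
cluster-id order (order-invariant, parallelizable by contract). Covariate
categories absent within a cluster make that coefficient inestimable there:
the indicator column is dropped for that cluster's fit and the cluster is
excluded from that coefficient's estimate set only, with the reason logged.
Non-converging or rank-deficient clusters are excluded entirely.

## Sampling comparators and the benchmark engine

`draw_srs` samples round(f·N) subjects without replacement (all visits kept,
weight 1/f); `draw_strs` samples round(f·N_h) per stratum (minimum 1,
logged), weight N_h/n_h; `bootstrap_resample` draws subjects with replacement
to the original count, giving duplicates fresh ids so the fitter treats them
as independent, provenance retained. Fractional sizes use round-half-to-even;
the rule is stated rather than inherited because no consistent convention
reproduces the motivating application's printed sample sizes.

`run_resampling_study` fits the full-data benchmark once, then per replicate
draws the sample and refits per strategy (SRS unweighted — selection
probabilities are equal; StRS by weighted pseudo-likelihood with sandwich
SEs). The partition-and-pool strategy and the fraction-1.0 "full" strategy
are deterministic given the data and are computed once. Replicate seeds
spawn deterministically from the plan's master seed, so identical inputs give
byte-identical summaries. The "simulated 95% CI" is the 2.5/97.5 percentile
interval of replicate estimates (a normal-approximation interval is emitted
alongside, since the construction is not standardized); coverage is the
fraction of replicate-level Wald intervals containing the benchmark. A
strategy with more than 20% failed replicates is summarized with a prominent
warning.

## Synthetic cohorts

The generator emulates a national clustered diabetes cohort: 23 clusters by
default (assigned to five regions in blocks matching the published regional
shares), up to 5 annual visits with monotone dropout (retention 0.95 per
visit — a plausible rate; the source application reports attrition but no
rate), and covariate margins matching the published cohort profile (race
62/12/14/12%, comorbidity count 57/28/11/4%, 98% male, 65% married, 62%
urban, mean disability 12%). Default continuous-outcome coefficients are the
published full-cohort estimates (minority-race effects 0.46/0.29/0.25,
comorbidity 0.01/0.04/0.11, intercept 7.54); coefficients the source does
not report (time, sex, marital status, urban residence, disability) were
fixed once at small plausible values so the mean outcome lands near the
published 7.4%. These defaults are generator calibration, not reproduction
targets. Variance components default to σ_b = 1.0, σ_e = 0.7 (continuous)
and σ_b = 1.0 on the logit scale (binary), realistic for HbA1c.

Per-cluster true coefficient vectors are β + ν_v with ν_v ~ N(0, σ_v²)
per coefficient (σ_v = 0 by default: homogeneous), plus injected outlier
shifts for specific (cluster, coefficient) pairs — opposite-direction pairs
reproduce the extreme-cluster phenomenon. The binary outcome is generated
from its own logistic mechanism (so the logistic mixed model is correctly
specified in recovery tests); a threshold mode dichotomizes the latent
continuous outcome at 8.0 instead, mimicking dichotomization of an observed
measure. One seed sequence feeds four named substreams (covariates, cluster
effects, outcome noise, dropout) so toggling dropout does not perturb
covariate draws.

What the generator does **not** emulate: real comorbidity ascertainment,
informative dropout, within-subject autocorrelation beyond the random
intercept, measurement error in the outcome, or unequal cluster sizes unless
configured. Passing tests therefore demonstrate correctness of the
estimators under a correctly specified homogeneous (or explicitly
heterogeneous) data-generating process, not robustness to real-data
misspecification.

## Simulation scales and what the checks show

Test and acceptance-script problem sizes were chosen once, by design-time
power analysis, to make each qualitative claim decidable at desk scale:

* **Recovery.** 200 replicate homogeneous cohorts (20 clusters × 2000
  subjects): the pooled minority-race estimate is unbiased within 2
  Monte-Carlo SEs. Across larger seed batches a small positive bias of
  roughly 1–2% relative is discernible — the familiar small-sample bias of
  inverse-variance pooling with estimated weights at ~100 subjects per
  cluster; it shrinks with cluster size.
* **Calibration.** On 1000 simulated homogeneous 20-cluster panels the Q
  test rejects at ~5% and the pooled random-effects interval covers the
  truth ~95% (the one-step estimator's usual slight undercoverage is within
  the accepted band).
* **Sampling contrast.** For the continuous outcome, 5% subsamples (SRS and
  weighted StRS) are unbiased for the full-data fit within Monte-Carlo
  error. For the binary outcome the comparison uses deliberately small
  cohorts (8 clusters × 1000 subjects, so a 5% subsample holds ~50
  subjects): at that size the mixed-logit subsample fits are unstable
  (roughly a quarter fail or separate) and their mean estimates deviate from
  the full-data benchmark several times more than the pooled estimates do —
  the scaled-down analogue of subsampling being unreliable for non-gaussian
  outcomes while partition-and-pool tracks the full fit.
* **Screening.** On 23-cluster panels with an injected ±6-SE pair, the
  screen excludes exactly the injected pair in ≥95% of replicates and the
  post-exclusion pooled mean is unbiased.

## Numerical conventions and degenerate inputs

* Variance parameters live on unconstrained scales; estimates below 1e-8 are
  reported as exact zeros with a boundary flag (a perfect within-subject fit
  yields residual variance 0, flagged, with exact fixed effects).
* Rank-deficient designs raise an error naming the collinear terms in
  declaration order; categorical expansion uses fixed declared reference
  levels and declaration-order column names, so coefficient indices are
  stable across clusters and replicates.
* Pooling a single estimate passes it through with a warning; Q ≤ df
  truncates σ̂_v² to zero, making the random-effects and fixed-effects
  results identical; all-equal estimates give Q = 0, I² = 0, p = 1.
* The DerSimonian–Laird computation matches an independent established
  implementation to 1e-8 over randomized estimate sets, including the
  truncation at zero (which that implementation omits).

## Limitations

* One level of nesting only (subjects in clusters); no crossed random
  effects; binary outcomes support a random intercept only and the logit
  link only.
* Pseudo-likelihood here is exact weighted ML/REML, not a linearization
  (RSPL-style) scheme; weighted results can therefore differ slightly from
  linearization-based software on the same data.
* The published form of the weighted marginal covariance in the motivating
  methodology is dimensionally inconsistent; this package uses the standard
  weighted form (weights as frequency multipliers of subject
  log-likelihoods) and documents the choice rather than guessing intent.
* Missing data are handled by dropping incomplete rows (logged), which is
  valid under covariate-dependent missingness only; no imputation.
* Meta-regression treats per-cluster standard errors as known; with few
  subjects per cluster this induces the small pooling bias noted above and
  slight undercoverage of the one-step interval.
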