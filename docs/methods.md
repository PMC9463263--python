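# Methods

## The biometric model

The classical twin design identifies variance components from the
contrast between MZ co-twins (who share all segregating variants) and
DZ co-twins (who share half on average).  `twinsleep.biometric` encodes
the expected twin-pair covariance with cross-twin coefficients 1 / 0.5
for additive effects, 1 / 1 for shared environment and 1 / 0.25 for
dominance.  C and D are never co-estimated: with twins reared together
they are not jointly identified, so the model *kind* (ACE, ADE, AE, CE,
E) fixes which middle component exists.  The conventional screen — fit
ACE when the DZ correlation exceeds half the MZ correlation, ADE when
it falls below — is implemented in `falconer_estimates` and used by the
model-selection driver to pick the three-component candidate.

Components are *direct symmetric*: free symmetric matrices rather than
Cholesky products.  Individual components may go indefinite during
optimization; only the total phenotypic covariance must be positive
definite, enforced by a large finite likelihood penalty wherever a
Cholesky factorization of the implied covariance fails.  This choice
avoids the boundary bias and type-I error distortion that constrained
(Cholesky) parameterizations introduce, at the cost of occasionally
returning slightly out-of-band standardized estimates — which is the
behaviour the downstream decomposition functions expect and flag.

## Likelihood

`twinsleep.likelihood` implements full-information maximum likelihood
over twin pairs:

* Continuous traits contribute a multivariate normal log density at
  their covariate-adjusted means.
* Ordinal traits are liability-thresholded: identification fixes the
  total liability variance at 1 (the non-shared-environment diagonal is
  substituted, not estimated) and the liability mean at 0, with
  thresholds free and covariates shifting the mean.  Thresholds are
  parameterized as a first cut plus positive increments, so ordering is
  maintained by box constraints alone.
* Mixed records are evaluated by conditioning the ordinal liabilities
  on the observed continuous traits analytically, reducing the
  rectangle integral to at most the number of observed ordinal values
  (six at this package's scale).
* A pair with a missing co-twin contributes the marginal single-twin
  likelihood; within-twin partial missingness marginalizes the same
  way.  No imputation is ever performed.

Rectangle probabilities must be *deterministic* or -2LL values would
not reproduce.  scipy's multivariate normal CDF is randomized between
calls, so `twinsleep.mvnorm` computes rectangles itself: closed-form
(normal CDF) in one dimension, composite Gauss-Legendre quadrature of
the conditional band in two (accurate to ~1e-12), and the Genz
separation-of-variables transform on an unscrambled Sobol point set
pushed through a tent map in three and above.  The default 4096-point
set gives absolute errors around 5e-7 (verified against dense
quadrature and scipy at loose tolerance); tests that need 1e-6 on log
probabilities raise the point count.  Variables are reordered
narrowest-band-first before the transform, the standard accuracy trick.

Two evaluation paths exist.  All-continuous models without covariates
use sufficient statistics per (zygosity class, missingness pattern) —
count, mean and scatter — making one -2LL evaluation O(patterns x p^3)
regardless of cohort size, with analytic gradients obtained by
contracting dF/dSigma into per-component weight matrices and chaining
through each model's parameterization.  Everything else (ordinal
traits, covariates) falls back to the per-pair path with finite
-difference gradients.  Optimization is L-BFGS-B with box bounds and
seed-controlled jittered restarts; convergence tolerance 1e-11
(relative) on -2LL.

Covariates follow the cohort's design: age is linearly rescaled to
[0, 1] before entering the means, sex is coded 0/1, and opposite-sex DZ
pairs use each twin's own sex covariate with no other sex-specific
parameters.  Thresholds are constrained equal across sexes; sex acts on
the liability mean only.

Confidence intervals are profile-likelihood: bisection for the
parameter value at which the re-optimized -2LL rises by the chi-square
quantile, with boundary and open-interval flags.  Derived quantities
are profiled by reparameterization — e.g. the univariate AE model is
re-expressed with (h², total variance) as free parameters so h² bounds
come from the generic profiler.  AIC is -2LL + 2k; because other
software's AIC may differ by an additive constant, only AIC
*differences* between models fitted to the same data are meaningful.

## Model zoo and nesting

The pathway models restrict the free multivariate AE covariance:

* Independent pathway: A = a a' + diag(a_s), E = e e' + diag(e_s), one
  common genetic and one common environmental loading vector plus
  trait-specific residuals; first loadings constrained nonnegative to
  fix reflection.
* Common pathway: a latent phenotype with unit variance split as
  aL² + eL² = 1 transmits through loadings lambda, so
  A = aL² lambda lambda' + diag(a_s); the latent heritability is
  directly readable as aL².  The three-factor variant (duration +
  efficiency; subjective quality + latency + medication; disturbances +
  daytime dysfunction) gives each factor its own split and correlates
  the factors' A parts and E parts through free correlation matrices
  (correlations are a configuration switch; the default frees them).

These are exactly nested: a common-pathway solution maps to independent
-pathway parameters (a = sqrt(aL²) lambda, e = sqrt(1-aL²) lambda) and
an independent-pathway solution maps to the free multivariate model by
expanding the implied matrices.  The selection driver fits the chain in
that order and warm-starts each richer model from the mapped optimum of
the poorer one, so the -2LL ordering multivariate <= independent <=
common holds on every dataset up to optimizer tolerance by
construction, not by luck.  Likelihood-ratio tests are reported along
the nesting chain, AIC everywhere.

## Synthetic cohort generator

`twinsleep.simulate` draws pair liabilities from the exact expected
covariance per zygosity group, then applies, in order: covariate
effects on the liability means, right-skew emulation, ordinal
thresholding, and co-twin masking.  Defaults emulate the reference
cohort:

* group sizes (total/complete pairs): MZ male 158/120, DZ male 197/171,
  MZ female 213/194, DZ female 218/187, DZ opposite-sex 392/279 — 1178
  families, 2129 respondents;
* age truncated-normal, mean 53.7, SD 7.3, range 43-71; sex fixed by
  group, with random twin ordering in opposite-sex pairs;
* ground truth: the published seven-component AE architecture
  (`published.py`): h² = 0.23, 0.25, 0.21, 0.32, 0.30, 0.40, 0.36 with
  the published rA/rE matrices, verified positive definite as printed
  (minimum eigenvalues 0.11 and 0.31);
* ordinal components (subjective quality, medication, daytime
  dysfunction): four categories with thresholds chosen to concentrate
  mass in the low categories (medication especially: ~75% in category
  0), the qualitative pattern of population sleep questionnaires;
* skewed components (latency, disturbances): liabilities are
  exponentiated, giving positive lognormal scores rescaled to unit
  variance.  The scores are deliberately *not* recentred: the analyst
  -facing log(x+1) transform requires nonnegative input, and the point
  of the skew emulation is to give that transform real work to do;
* age/sex covariate slopes default to zero — the reference analyses
  adjusted for age and sex but did not report effect sizes, so zero is
  the neutral choice, overridable per trait in the configuration;
* incomplete pairs: a seed-controlled random subset of co-twins is
  masked to hit the configured complete counts (or a `missing_rate`).

`liability_scale=True` bypasses skew and thresholding and emits the raw
liabilities — the mode used for parameter-recovery studies, where the
estimand lives on the liability scale.

What the generator does *not* emulate: item-level responses,
gene-environment interaction, assortative mating, sex-specific genetic
architecture (qualitative or quantitative), and selective attrition
correlated with phenotype (masking is at random).  Passing recovery
tests therefore shows the estimator is correct under the classical twin
assumptions, not that those assumptions hold in any real cohort.

Descriptive cross-twin correlations are double-entered (both twin
orderings) with DZ groups pooled by default; ordinal traits use a
two-step polychoric estimate (thresholds from margins, correlation by
bounded 1-D likelihood optimization over exact bivariate rectangles).

## Confirmatory factor analysis

The CFA treats the seven components as continuous and maximizes the
Wishart likelihood of the sample covariance of one randomly selected
twin per family (complete cases; singletons contribute their observed
twin deterministically).  This continuous treatment is the default
because the univariate analyses of the same cohort found ordinal and
continuous treatments agreed; a polychoric input matrix can be passed
explicitly via the covariance-matrix entry point.  Factors are
identified by unit variance.  Index conventions, fixed and documented
because other software shifts some by constants: RMSEA uses n-1 in the
denominator with a 90% CI by noncentral chi-square inversion; SRMR
covers off-diagonal residual correlations only; CFI/TLI use the
independence-with-free-variances baseline, TLI truncated at 1; BIC is
on the chi-square deviance scale, chi² + k ln(n).

## Problem sizes and numerical choices

The test suite exercises recovery at the emulated cohort scale (1178
families) for the continuous 7-trait model, where the sufficient
-statistic path makes a full fit take well under a second; replicated
experiments (recovery rates, model-selection frequencies, CI coverage)
use 25-150 replicates at that scale or below.  Ordinal-likelihood fits
are validated at a few hundred pairs — their per-pair evaluation is
orders of magnitude slower, and the estimator is the same code path
regardless of n.  Degenerate inputs are rejected with named errors
(non-PSD ground truth names the offending matrix; too-few complete
pairs names the zygosity group; zero-variance traits are named in
standardization), and undefined etiological correlations (zero
component variance) are flagged rather than silently NaN.

## Known limitations

* Sex-limitation models (qualitative/quantitative) are out of scope;
  DZ opposite-sex pairs share the pooled DZ expectation.
* The direct-symmetric fit can return h² marginally outside [0, 1];
  consumers should read the flags rather than clip.
* Profile CIs for arbitrary derived quantities of the multivariate
  model (e.g. a specific rA) would require per-quantity
  reparameterization and are not exposed; raw-parameter and univariate
  -h² profiles are.
* The 3-factor common-pathway gradient is numerical; its fits are
  noticeably slower than the 1-factor model's.
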