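# Methods

This note documents the models, their assumptions, the defaults and the
numerical choices behind `twintaste`, and what the synthetic-data tests do
and do not establish about real data.

## The classical twin design

The CTD decomposes the variance of a trait measured on same-sex twin
pairs into additive genetic (A), shared/common environmental (C) *or*
dominance genetic (D), and unique environmental (E) components.  E
absorbs measurement error and is always present; C and D are mutually
exclusive in a two-group (MZ/DZ) design because both are identified only
through the same two covariance contrasts.  Expected moments:

| quantity | value |
| --- | --- |
| within-person variance | A + C + D + E |
| MZ co-twin covariance | A + C + D |
| DZ co-twin covariance | ½A + C + ¼D |

Assumptions inherited from the design: equal environments across
zygosity, random mating, no gene–environment correlation or interaction,
and (for D) the standard ¼ coefficient for fraternal dominance sharing.
The saturated model (unstructured per-zygosity means and covariances)
exists to test the homogeneity assumptions — equality of means and
variances across twin order and zygosity — by likelihood-ratio tests
against equated submodels.

### Direct symmetric parameterization

Variance components enter the expected covariance matrices directly and
are **unbounded in sign**.  Compared to path-coefficient (Cholesky)
parameterizations this removes boundary-induced estimation bias, keeps
likelihood-ratio tests on the usual chi-square reference (no boundary
mixture), and allows the small negative point estimates that honest
two-group designs sometimes produce.  Consequently a fitted "variance"
slightly below zero is a legitimate outcome, and standardized shares can
fall marginally outside [0, 1]; derived quantities flag and optionally
clip such cases.

### Estimation

Full-information maximum likelihood over per-family Gaussian blocks.
Families are grouped by (zygosity, missingness pattern); incomplete pairs
contribute the marginal univariate likelihood of the observed member.
Mean covariates (sex; age, centred) affect the mean model only, with
identical coefficients across co-twins.  The mean parameters are profiled
out in closed form by GLS at each candidate component vector, so the
numerical search runs over only the 2–3 (univariate) or up-to-18
(trivariate) component parameters: Nelder-Mead from moment-based starting
values (components solved from observed MZ/DZ covariances) with jittered
restarts for the univariate models, BFGS + Nelder-Mead polish for the
multivariate models.  A non-positive-definite candidate covariance is
rejected with a large penalty.

Degrees of freedom are reported as free-parameter counts, with observed
value counts stated separately; AIC = −2LL + 2·(free parameters).

### Profile confidence intervals

Likelihood-based CIs are the set of parameter values whose profiled −2LL
stays within the chi-square(1) quantile (3.841 at 95%) of the minimum.
For standardized shares the model is reparameterized as (shares, total
variance) so the constraint is imposed exactly; for the multivariate
derived quantities (ρA, h²_b) the A cross-covariance is substituted by
the expression the fixed derived value implies.  Bounds are located by
Brent's method from the fitted point outward; a bound that never crosses
the threshold inside the search range is reported open-ended (±inf).
Saturated-model twin correlations use the Fisher-z approximation instead
— they serve as descriptive model-selection input, not inferential
endpoints.

### Multivariate models

For k traits the per-family observation vector stacks both twins
(length 2k, missing entries dropped per family).  Component matrices
`Σ_A, Σ_C, Σ_E` are symmetric k × k; per-trait component inclusion zeroes
the excluded trait's row/column, and the E block is always full.  The
full bivariate/trivariate ACE models have 11/21 free parameters (k means
plus component entries); the saturated reference (per-zygosity
unstructured 2k-moments) has 28/54, giving the comparison-chain
differences of 17/33 degrees of freedom.  The saturated reference is
fitted by per-zygosity sample moments, which is the exact MLE for
complete pairs; incomplete pairs are excluded from that reference only
(with a warning) — the structured models handle them by FIML.

Derived quantities: ρA = σ_A12/√(σ²_A1σ²_A2), ρE analogously, and
h²_b = σ_A12/(σ_A12 + σ_C12 + σ_E12), the share of the phenotypic
cross-trait covariance attributable to additive genetics.

## Crossed variance partitioning

Ratings (one twin per pair, to avoid familial pseudo-replication) follow
a Gaussian random-intercept model crossed in individual, image and
exposure (presentation index), with all pairwise interactions and a
residual.  Estimation is REML: the residual variance is profiled
analytically, the remaining components are optimized on the log-ratio
scale (so they stay nonnegative; a ratio at the lower bound, about 2e-6,
is reported as a structural zero), and each likelihood evaluation goes
through Henderson's mixed-model equations.  The individual × image block —
by far the largest — has a diagonal normal-equations block and is
eliminated by a Schur complement, leaving a dense Cholesky factorization
of only the small remainder; this makes the criterion cheap enough for
quasi-Newton iteration with numerical gradients.  The criterion includes
all constants and matches lme4's `REMLcrit` to ~1e-2 on shared fixtures
(one test runs lme4 through Rscript as an independent oracle).

Identifiability: the individual × image interaction is separable from the
residual only through repeated presentations.  With no repeats the
exposure terms and the interaction are dropped (merged into the residual)
with a warning.  For balanced complete designs a closed-form ANOVA
(expected-mean-squares) estimator is provided as an independent
method-of-moments path; on balanced data it agrees with REML to
numerical precision, which the tests exploit.

VPCs are each component's share of the summed components and sum to one
exactly.

## Aesthetic metrics

* Pairwise agreement: Pearson correlation over the images both raters
  share, computed on repeat-averaged ratings; analysed on the Fisher-z
  scale, with means aggregated in z and back-transformed to r for
  reporting.  |r| = 1 is clipped to 1 − 1e-12 before the transform and
  flagged.
* Taste-typicality (mm2): correlation of a rater's profile with the mean
  profile of everyone outside their family ("mean minus two"), also
  repeat-averaged, analysed as Fisher z.
* Evaluation-bias: the rater's mean rating.
* UR pairs: each twin-order-2 member is matched to a twin-order-1 member
  of a different family and the same sex, greedily by smallest age
  difference after a seeded shuffle; each individual is used once.
  Greedy matching is O(n log n) and is verified against exhaustive
  assignment on small separated-age fixtures; on adversarial age
  configurations it can be marginally suboptimal, which is immaterial for
  its role as a similarity baseline.
* Principal axes: SVD of the column-centred, unscaled rating matrix on
  first pair members only; axis 1 (2) is sign-aligned to correlate
  positively with evaluation-bias (taste-typicality z) when alignment
  vectors are supplied.
* Agreement ANOVA: type III sums of squares with sum-to-zero contrasts
  (statsmodels OLS + anova_lm); partial η² CIs by noncentral-F inversion,
  Cohen's d CIs by noncentral-t inversion; Bonferroni multipliers fixed at
  3 (pair-class contrasts), 3 (domain contrasts) and 9 (class within
  domain).

QC defaults: reliability threshold 0.5 (strict `<` excludes), IQR fence
multiplier 3, two-sided (a one-sided option exists); quartiles use linear
interpolation (type 7).  Exclusions are per visual domain, so a pair can
continue as an incomplete pair elsewhere.  A zero-variance presentation
vector makes reliability undefined and excludes the rater (conservative).

## The synthetic-data generator

Latent traits: per-component trait × trait covariance matrices with the
exact CTD sharing structure (MZ share A and D draws; DZ A draws correlate
0.5 and D draws 0.25 via shared/unique splits; C shared within family; E
independent).  Pairs are same-sex (76% female by default), twins share an
age drawn uniformly from 21–68 years.  Default counts mirror a
discovery-sample-sized study: 558 MZ and 216 DZ pairs.

Rating layer, per domain (defaults: 65 images, 15 repeated, 1–7 scale,
grand mean 4):

    rating = 4 + (1 + 0.4·typicality)·image + 0.5·bias
             + idiosyncrasy + exposure + residual

with image sd 1.0, idiosyncrasy sd 0.7, exposure sd 0.1, residual sd 0.6.
The bias offset and typicality weight are deterministic functions of the
standardized latent traits, so the computed metrics inherit the
configured A/C/E structure; at these defaults the metric–latent
correlations are ≈0.97 (bias) and ≈0.93 (typicality), and the
individual-level VPC share lands near 40%, inside the 35–69% range the
three visual domains span.  The scale factors (0.4, 0.5) are free
calibration parameters: the raw-scale variance of the latent dimensions
is not observable separately from the rating noise, so they were chosen
once for realistic reliabilities (R_intra ≈ 0.8) and held fixed.

Clipping to the scale bounds and rounding to integers are available but
off by default: the model-validation and acceptance runs need exact
moment control, and clipping distorts variances.  Hence generated ratings
are continuous and can exceed the nominal bounds; declare a scale to
`read_ratings` only for genuinely bounded data.

What passing tests show — and don't.  The generator draws from exactly the
Gaussian models the estimators assume, so recovery tests establish
correctness of the likelihoods, optimizers and derived formulas, not
robustness to ordinal scales, rater drift, assortative mating,
gene–environment interplay or systematic exposure effects, none of which
are generated.  Metric-level heritabilities are attenuated relative to
the latent generating values by the metric's residual measurement noise
(roughly the squared metric–latent correlation), which is visible in the
end-to-end pipeline tests and is a property of real analyses too.

## Pipeline conventions

Model ladder per trait: the saturated fit supplies twin correlations;
ADE is the full model when r_DZ < ½·r_MZ, otherwise ACE; submodels
(AE/CE, then E) are tested against the full model and the most
parsimonious one with LRT p ≥ 0.05 is reported as final.  Ladder p-values
are unadjusted.  Multivariate specifications follow the univariate
finals (A/C included per trait accordingly).  The sensitivity stage
regresses taste-typicality and evaluation-bias on control-task scores
plus sex and age, and refits the final models on OLS residuals.

The VPC stage subsamples raters (default cap 120 per domain) because REML
cost grows quickly with the individual × exposure block; the cap is a
config knob, and estimates at the cap are unbiased, just less precise.

Every random step (UR matching, VPC subsampling, optimizer restarts,
simulation) derives from the single pipeline seed; a rerun with the same
configuration is bit-identical.

## Known limitations

* Ordinal/threshold liability models are out of scope; ratings are
  treated as Gaussian.
* No sex-limitation or opposite-sex DZ modelling; pairs are same-sex.
* Saturated multivariate reference requires complete pairs.
* The CTD identification caveats apply: with two zygosity groups, C and D
  cannot be estimated jointly, and all estimates are population- and
  environment-specific.
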