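# Methods

## The biometric model

All models are classical twin ACE decompositions on the liability scale.
Each trait's (latent) liability is standard normal and is the weighted sum
of three uncorrelated standard-normal factors — additive genetic (A),
shared environment (C), non-shared environment plus measurement error (E) —
with standardized paths `a, c, e` and variance shares `a² + c² + e² = 1`.
The identifying contrast is zygosity: A factors correlate 1.0 across
monozygotic co-twins and 0.5 across dizygotic co-twins (who share on
average half their segregating variants), C correlates 1.0 in both, E is
individual-specific.

For several traits the package supports two equivalent parameterizations:

- **correlated factors** — per-trait paths plus aetiological correlations
  `rA, rC, rE` between traits' factors.  The model-implied within-person
  cross-trait correlation is `rA·a₁·a₂ + rC·c₁·c₂ + rE·e₁·e₂` (each term is
  one "channel" of the phenotypic correlation, reported as %A/%C/%E after
  normalizing by their sum);
- **Cholesky** — lower-triangular path matrices per component, so factors
  introduced at earlier traits load on later ones.  Used for the
  trivariate prospective model, where baseline suicidality's and baseline
  OCS's factor sets both send directed paths to follow-up suicidality; the
  *unique* baseline-OCS → follow-up channel is the product of the
  second-column paths (`Λ[1,1]·Λ[2,1]` per component), i.e. the covariance
  not routed through baseline suicidality's factors.  Squaring a
  standardized path and multiplying by 100 gives its variance percentage.

Binary and ordinal traits are thresholded liabilities: category k is
observed when the liability falls between cut points τₖ₋₁ and τₖ.
Thresholds are shared across co-twins and may be shifted linearly by age
and sex ("threshold covariates").  Continuous traits enter either
pre-standardized (the default: the pipeline ln(x+1)-transforms, z-scores
and, via the sex covariate, adjusts questionnaire totals upstream) or with
free means/SDs.

## Likelihood and numerics

Fitting is raw-data full-information maximum likelihood: each pair
contributes the log joint probability of whatever it was observed to have.
Continuous blocks are multivariate-normal densities; ordinal blocks are
rectangle probabilities of the liability distribution conditioned exactly
on the continuous entries (conditional-normal factorization); missing
entries are marginalized by dropping dimensions, so singleton twins and
pairs lost to follow-up still contribute.

Rectangle probabilities are computed with deterministic integrators,
chosen so that -2LL is bit-reproducible across calls (scipy's MVN CDF is
randomized QMC and returns a different value on every call, which breaks
optimizer line searches and run-to-run comparability):

- dimensions 1–2: closed-form normal CDF and a vectorized bivariate-normal
  CDF (Genz's adaptation of Drezner–Wesolowsky; Gauss–Legendre order
  6/12/20 by |ρ|, separate expansion for |ρ| > 0.925; absolute error
  ~1e-14).  This is the hot path of all bivariate models.
- dimensions ≥ 3: quasi-Monte-Carlo sequential conditioning (Genz) on a
  fixed Richtmyer lattice with antithetic reflection (2×2048 points by
  default).  Each rectangle is integrated with its most constrained
  dimension first — that factor is then exact — which bounds the
  *relative* error of rare response patterns (~1–2%); absolute error is
  ~1e-5.  Rectangles sharing a variable ordering are evaluated as one
  vectorized batch, and pairs are grouped by response pattern, so the cost
  per likelihood evaluation depends on the number of distinct patterns,
  not the number of pairs.

Probabilities are floored at 1e-300 with a warning when any cell falls
below 1e-12 (a threshold configuration inconsistent with an observed
category yields a large finite penalty, never NaN).

**Optimization.**  Free parameters are unconstrained: variance shares are
normalized squares with the raw E coordinate pinned at 1 (the boundary
c² → 0 stays smooth), correlations pass through tanh, thresholds are a free
first cut point plus log-increments, and the trivariate Cholesky rows are
normalized across components with the raw E diagonal as the scale gauge.
L-BFGS-B with numerical gradients; multi-start uses a data-driven first
start (thresholds from observed margins, shares at ~1/3) plus
deterministically jittered restarts from a fixed sub-seed (default 5; the
expensive large-cohort fits in the examples use 1–2, which we observed to
reach the same optimum).  Non-convergence from every start is reported
explicitly, never as a silent partial result.

**Model comparison** uses -2LL differences (chi-square with the parameter
count difference as df) and AIC = -2LL + 2k; the simpler nested model is
preferred when the likelihood loss is non-significant or its AIC is lower
by ≥ 3.  The pipeline's ACE → AE reduction fits the full ACE model first
and tests the AE reduction when every C share is below 5%, accepting it if
the -2LL difference is non-significant.  (C-share "significance" is
assessed by this likelihood-ratio route rather than by first profiling a
CI for C, which would double the cost for the same decision.)

**Profile confidence intervals** solve `profiled(-2LL) = min(-2LL) +
3.841` (chi-square(1), 95%).  The profiled curve is computed by penalized
refitting: the reported scalar — which may be any smooth function of the
parameters, e.g. a variance share, rA, or %A — is pinned at trial values
with a quadratic penalty (weight 1e6 on unit scale) while everything else
is re-optimized from a warm start; brentq then finds the crossing.  Bounds
that run into the quantity's natural box (0 for shares, ±1 for
correlations) are truncated there and flagged.

## The synthetic cohort generator

The generator draws pair liabilities from the exact multivariate normal
the ACE model implies (cross-twin A blocks scaled 1.0/0.5, C 1.0, E 0),
adds covariate effects, then thresholds ordinal traits and optionally
skew-transforms continuous ones (`exp(s·liability)` affinely rescaled by
its theoretical log-normal moments to a target mean/SD — so the observed
score is positively skewed and the pipeline's ln(x+1) step is exercised
round-trip).  Components correlation matrices are validated (symmetric,
unit diagonal, PSD) at construction; the implied pair matrix is checked
again and the offending zygosity block named on failure.  Degenerate PSD
configurations (e.g. rA = 1) are legal and sampled via eigendecomposition.

Default cohort (the conditions the analyses target): ~30% MZ pairs, 3% of
pairs relabelled unknown zygosity (excluded by model fitting, with a
logged count), 58.8% female, two waves at ages 18 and 24 with pairwise
follow-up retention 25%, a skewed continuous OCS total (heritability 37%)
and a 6%-prevalence binary suicide-attempt item (heritability 61%) at 18
with rA = .42 / rE = .13 between them, OCS (38%) plus binary ideation
(24.2%) and attempt (5.3%) items at 24 with rA = .37 / rE = .29 to OCS,
and continuous depression/anxiety scores at both waves.  Cross-construct
values not pinned down by the bivariate analyses (e.g. OCS stability
rA = .60) are plausible mid-range values chosen once for internal
consistency and PSD-ness.

Attrition is **pairwise** (whole families drop from the follow-up wave):
registry follow-ups are mailed per household, and the choice is recorded
as an assumption — individual-level attrition is emulated instead by the
per-item missingness rate (default 0), which also exercises FIML.
A single integer seed drives every stochastic step through spawned
sub-streams.

What the generator does *not* emulate: item-level response processes (the
tetrachoric-PCA fixture generates binary items from a separate orthogonal
factor model), informant (parent) reports, non-random attrition,
sex-limitation of the genetic architecture, and assortative mating.
Passing tests therefore demonstrate correctness of the estimators under
the liability-ACE data-generating process, not robustness to violations
of it.

## Phenotypic analyses

- `log_standardize`: ln(x+1) then z-score.  The +1 offset handles the
  zeros of count-like symptom scales; base e throughout.
- `composite_suicidality`: OR-combination; positive if either item is
  endorsed, negative only if both observed 0, missing when one item is
  missing and the other 0 (an endorsement cannot be ruled out).
- `tetrachoric`: two-step ML (thresholds from margins, Brent search on ρ,
  tolerance 1e-8); empty cells pin the estimate at ±1 with a flag.
  `pca_tetrachoric` eigendecomposes the pairwise matrix after a
  nearest-PSD repair (eigenvalue clipping, flagged) and varimax-rotates
  the retained components; the retention count is fixed by configuration
  (default 4).
- `cluster_robust_logistic`: statsmodels GLM fit (IRLS to tol 1e-12), then
  the plain cluster sandwich H⁻¹(Σ_c s_c s_cᵀ)H⁻¹ aggregated at family
  level with *no* small-sample factor — making estimates and SEs exactly
  invariant under within-cluster duplication — and Wald 95% CIs on the
  log-odds scale.  Separation is flagged and the affected CIs marked
  unreliable.  Missing data: listwise deletion per model, with the n used
  reported per tier.

## Pipeline conventions

Adjustment tiers run in order (unadjusted / +depression /
+depression+anxiety; the prospective stage instead adds baseline attempts
before the symptom covariates), all models controlling for age and sex.
Twin models run only for trait pairs whose latent-scale (polyserial /
tetrachoric) correlation exceeds 0.2 in absolute value — decomposing
weaker associations gives unstable solutions — and the gate threshold is
configurable.  No multiple-testing adjustment is applied; per-model
significance stars are reported as-is.  The JSON bundle is
deterministic for a fixed plan seed (sorted keys, full-precision floats).

## Problem sizes used in the examples and checks

Bivariate recovery runs at 20,000 MZ + 20,000 DZ pairs (the scale at which
the genetic correlation and %A are recovered to a few points); univariate
recovery at 10,000 + 10,000; profile-CI coverage at 150 + 150 pairs over
20–30 replicates; the trivariate model's property checks at 1,500 + 1,500
pairs with ~70% follow-up retention.  The acceptance script reports the
Monte-Carlo mean of each recovered estimate over five replicate cohorts
(the single-cohort %A and binary-heritability estimators have MC SDs of
roughly 4 points at these sizes).

## Known limitations

- Ordinal traits with many categories multiply the distinct response
  patterns and hence the ≥3-dimensional integration cost; short symptom
  subscale scores are modelled as binary by default (category count
  configurable).
- The trivariate model's unique-channel %A/%E split is weakly identified
  at realistic sample sizes (its profile CIs can span 0–100); point
  estimates should be read with their intervals.
- No sex-limitation, dominance, or rater-bias models; DZ pairs are pooled
  regardless of sex composition, with sex entering only as a covariate.
- Profile CIs assume the chi-square(1) calibration, which is conservative
  at boundary-truncated parameters.
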