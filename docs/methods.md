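# Methods

This note records the statistical model, estimation conventions,
numerical choices and known limitations of `factorgwas`, at the level
of detail a user needs to interpret its output or modify it.

## LD-score regression engine

For trait pair (a, b) and SNP j the model is
`E[z_aj z_bj] = c_ab + x_j * sigma_ab` with
`x_j = sqrt(N_aj N_bj) * l_j / M` (univariate: `x_j = N_j l_j / M`,
slope = SNP heritability). Both coefficients are estimated by weighted
least squares in two passes. Pass one weights by `1 / max(l_j, 1)`
(LD oversampling) only; pass two adds the reciprocal of the approximate
regressand variance evaluated at the pass-one coefficients:

    univariate:  var(z^2)      ~ 2 (a0 + b0 x)^2
    bivariate:   var(z_a z_b)  ~ (a0 + b0 x)^2 + (a_a + b_a x_a)(a_b + b_b x_b)

The pass-one coefficients enter these weights unclipped, with the
variance floored at 0.05: clipping would break two exact identities the
package tests — a trait regressed against its own copy must reproduce
the univariate h² regression weight-for-weight, and negating one
trait's Z must negate its row/column of S without changing magnitudes.

Standard errors come from a delete-a-block jackknife over `n_blocks`
(default 200) SNP blocks contiguous in the panel's position sort; the
multi-trait sampling covariance **V** is the joint jackknife covariance
of the delete-one slopes across all half-vectorized elements of **S**,
so `diag(V)` equals the squared per-pair SEs by construction. The vech
convention everywhere is the column-major lower triangle including the
diagonal; every consumer of V assumes it.

`standardize` maps S to the correlation scale and transforms V by the
delta-method Jacobian of `r = S_ab / sqrt(S_aa S_bb)`; rows for
diagonal elements become exactly zero, and the map is idempotent.

Indicator screening applies two rules: SNP heritability must be
one-sided significant (`h2/se >= 1.645` by default; the threshold is a
configuration choice, since "statistically significant" fixes the
criterion but not the alpha), and any trait whose |r_g| exceeds 0.9
with two or more other surviving traits is dropped as multicollinear in
a single simultaneous pass. On the packaged 11-trait correlation
matrix this removes exactly the NIH G6 component (r_g 0.947 and 1.044
with two other tests).

## PSD smoothing and the Z-difference filter

Covariance matrices assembled pairwise from cohorts with very unequal N
need not be positive semidefinite. `nearest_psd` clips eigenvalues at a
floor (default 1e-10) and reconstructs — the Frobenius-nearest matrix
with spectrum above the floor, one deterministic pass, no
alternating-projection refinement (unnecessary at 9–12 dimensions). S
and V are both smoothed. Because smoothing perturbs the fitted moments,
the factor GWAS is run under the pre- and post-smoothing matrices
whenever smoothing changed anything, and a SNP is removed if any
factor's |Z| differs by strictly more than 1 between the runs (a
difference of exactly 1 survives). Which Z the published procedure
compared (factor-effect vs indicator-covariance) is not documented;
comparing factor-effect Z on *any* factor is this package's policy, the
conservative reading.

## Genomic confirmatory factor models

A `ModelSpec` fixes indicators, factors, the loading pattern, factor
(co)variances, residual (co)variances and correlated residual pairs;
identification is by unit factor variance (standardized solutions), and
factor covariances default to fixed zero. The nine-model zoo covers a
common-factor model; correlated three-factor (shifting / working
memory / inhibition) models with and without an orthogonal substitution
factor over the two symbol–digit substitution tasks; and bifactor
models adding an orthogonal general EF factor, including the endorsed
bifactor with working-memory and substitution factors and four
modifications of it. The prospective-memory / ALSPAC working-memory
pair carries a free correlated residual in all models except the
common-factor model (whose published df forces its absence).

**Two-indicator specific factors and identification.** An orthogonal
factor with exactly two loadings and both residual variances free is
empirically under-identified: only the loading product enters the
moments, leaving a flat direction that makes the information matrix
singular (the fit reports a model error rather than fabricating SEs; a
spec with this structure is kept in the package as
`endorsed_model_literal` to document the behaviour). All substitution
variants therefore fix the CHARGE DSST residual variance to 0 — the
same device the source analysis used in its three-factor substitution
model — making the operational endorsed model a 24-parameter spec. The
substitution-is-shifting variant, whose third substitution loading
restores identification, keeps all residuals free.

## Estimation

Parameters minimize the diagonally weighted least-squares criterion
`(s - sigma(theta))' diag(V)^{-1} (s - sigma(theta))`. The optimizer is
a projected Levenberg–Marquardt with analytic Jacobian of
`sigma(theta)`, generous box bounds (|loading| ≤ 4·SD-scale, residual
(co)variances within ±4·variance-scale, SNP paths within ±2) whose only
purpose is to stop divergence along Heywood ridges, convergence by
ridged Newton decrement (< 1e-15·(1+F)) or stall detection, and an
L-BFGS-B + polish fallback with five seeded jitter restarts on failure.
Negative free residual variances are flagged (Heywood), never
constrained away. Standard errors use the full-V sandwich
`(D'WD)^{-1} D'W V W D (D'WD)^{-1}` with `W = diag(V)^{-1}`.

**Model chi-square convention.** The statistic is the residual-based
quadratic form
`T = res' [V^{-1} − V^{-1}Δ(Δ'V^{-1}Δ)^{-1}Δ'V^{-1}] res` evaluated at
the DWLS estimates. For a correctly specified model T is asymptotically
chi-square on `df = moments − k` for any consistent estimator, so its
expectation is df and nested differences are asymptotically chi-square
on the df difference — the property the Q-SNP test relies on. T is not
numerically comparable to chi-squares printed by other software with
other conventions; the package exercises it only through its
distribution (calibration tests) and the identities `AIC = chi2 + 2k`,
`df + k = t(t+1)/2`. V inverses are ridged (up to 1e-4 of the mean
diagonal) only if numerically singular.

Fit indices: `AIC = chi2 + 2k`;
`CFI = 1 − max(chi2_m − df_m, 0)/max(chi2_b − df_b, chi2_m − df_m, 0)`
against the independence baseline (all covariances fixed 0, variances
free), clipped to [0, 1]; SRMR is the root mean square of residual
moments standardized by the observed variances, over the lower triangle
including the diagonal. Absolute-fit labels: CFI ≥ 0.95 / SRMR < 0.05
good, CFI ≥ 0.90 / SRMR < 0.10 acceptable, joint label the weaker of
the two.

`genetic_multiple_regression` solves the genetic normal equations
`beta = S_pp^{-1} S_po` on the stack's scale and propagates V through a
central-difference Jacobian of beta (step 1e-6) — the design used to
control latent-factor associations for general cognitive ability and
processing speed.

## Per-SNP factor GWAS

Each SNP enters as an exogenous standardized variable:
`cov(SNP, trait_i) = z_i / sqrt(N_i)`, SNP variance fixed to 1, with
sampling variances `1/N_i` and zero assumed cross-terms appended to V
(the fixed SNP variance is not a fitted moment). Standardizing the
genotype rather than scaling by 2·MAF(1−MAF) affects the effect-size
scale only, not Z or p; MAF is optional in inputs. The measurement
model is re-estimated at every SNP (warm-started from the SNP-free
solution; for null SNPs the measurement estimates move by < 0.02, a
tested regularity), with free SNP→factor paths; the factor disturbance
variances stay fixed at 1, so factor totals are `1 + b²` — negligible
at per-SNP effect sizes. Q-SNP is the chi-square difference between
this common-pathway fit and an independent-pathways fit with free
SNP→indicator effects, on `df = indicators − factors` (the published
procedure names only the p threshold, 5e-8; the df convention is this
package's). Under the moment model with disjoint cohorts both the
factor p-values and the Q-SNP size calibrate (KS-uniform p-values; Q
rejection ≈ 5% at alpha 0.05, mean Q ≈ df over 2,000 null SNPs); with
shared samples the zero-cross-term assumption in the SNP block of V is
an approximation. The per-factor output reports the chi-square-implied
effective sample size `median(1/SE²)` — a reporting convention, not an
estimate of any cohort's N.

## Post-GWAS

Clumping scans genome-wide significant SNPs (p < 5e-8) by ascending p
(ties: position, then rsID): independent significant SNPs are mutually
below r² = 0.6, lead SNPs mutually below r² = 0.1, and each pruned SNP
is assigned to the first (smallest-p) selection that absorbed it, so
every significant SNP is accounted for exactly once. Risk loci span
each lead's assigned SNPs and merge within 250 kb on a chromosome.
These defaults are the annotation-platform conventions the published
analysis relied on; all are configurable, and the LD table is a plain
caller-supplied pair list (no LD reference ships with the package).
The novelty filter removes, in order, rsID matches with prior
significant SNPs, SNPs with r² strictly above 0.6 to a prior
significant SNP (boundary 0.6 survives), and loci overlapping a prior
locus by ≥ 1 bp (1-based closed intervals), writing an audit trail
naming the removing rule per item.

## Synthetic data generator

Summary statistics are drawn at the Z level from exactly the moment
structure the estimators assume: per SNP,
`z ~ MVN(0, l_j · diag(sqrt(N)) S diag(sqrt(N)) / M + C)`, independent
across SNPs, with `S = Λ diag(factor_h2) Λ' + diag(specific_h2)` from a
known loading matrix and `C` the intercept matrix (unit diagonal;
off-diagonal = shared-sample fraction × phenotypic correlation, the
LDSC cross-trait intercept). LD scores follow a shifted gamma law
(mean 10, shape 2, floored at 1) by default. The demo configuration
mirrors the study design: nine cohorts at the published sample sizes
(4,611–162,335), generating heritabilities equal to the published
SNP-h² estimates, a bifactor architecture (general factor ≈ 55% of each
trait's genetic variance; working-memory and substitution factors ≈ 25%
for their indicators; DSST entirely factor-determined, matching its
fixed-zero residual), 80% sample overlap among the five biobank tests
with phenotypic correlation 0.25 (the within-biobank overlap is not
published; both are free parameters), and sign-flipped output for the
traits distributed on a higher-is-worse scale. M defaults to 50,000
SNPs — large enough for stable LDSC at desk scale while keeping the
full acceptance run under a minute of simulation time.

What the generator does **not** emulate: LD block structure (SNPs are
exchangeable given their LD score), MAF-dependent architecture,
annotation-stratified heritability, population stratification, or
cross-cohort allele mismatches beyond what the harmonization tests
construct directly. Passing recovery and calibration tests therefore
show the estimators are correct *under their own assumptions*, not that
those assumptions hold in real cohort data.

## Problem sizes used by the tests

Unit tests run on 4,000–30,000-SNP panels with 40–100 jackknife blocks;
the acceptance checks use the 50,000-SNP / 200-block configuration,
2,000 SNPs per calibration suite, and a 20-SNP clumping toy against an
exhaustive oracle. The end-to-end pipeline demo restricts the per-SNP
scan to a few hundred SNPs (`gwas_max_snps`), since the reference path
refits the full model per SNP (~6 ms each); scanning a full panel
scales linearly and can be distributed trivially.

## Known limitations

- The reference per-SNP path refits all measurement parameters; a
  frozen-measurement fast path is deliberately not the default.
- The sampling covariance between SNP-trait covariances is assumed
  diagonal (zero cross-terms), exact only for disjoint cohorts.
- Chi-square values are convention-bound (see above); only their
  distributional properties and AIC/df identities are meaningful across
  software.
- Fitting the model zoo to the packaged published correlation matrix
  uses a diagonal-V surrogate from the printed standard errors; model
  ranking under that surrogate need not reproduce rankings obtained
  with a full sampling covariance, and estimate-level agreement with
  published fits is not expected.
- Multi-ancestry panels, INDELs, genome-build liftover and
  imputation-quality filtering are out of scope.
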