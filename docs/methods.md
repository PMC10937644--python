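# Methods

This note documents the models, numerical choices and known limits of
`netmr`: the estimators, the mediation arithmetic, and the synthetic
multi-trait study generator the test suite is built on.

## The causal model

The package targets a network (two-step) MR design. A standardized
exposure X acts on K binary outcomes both directly and through J
quantitative mediators:

    X      = G_x β_x + γC + ε_x                      var(X) = 1
    M_j    = a_j X + G_j β_j + γC + ε_j              var(M_j) = 1
    logit P(Y_k = 1) = α_k + d_k X + Σ_j t_jk M_j + γ_y C [+ pleiotropy]

with G the dosage matrices of each trait's own SNPs and C a small set of
covariates (sex, age, four ancestry-PC analogues). The estimands are the
per-SD total effect c_k = d_k + Σ_j a_j t_jk, the mediator direct effects
t_jk, and the proportion mediated p_jk = a_j t_jk / c_k.

## Estimators

All weighted regressions use inverse outcome-variance weights 1/σ_Y².
"Random effects" throughout means multiplicative overdispersion: the model
SE is inflated by √max(1, Q/df), the floor keeping underdispersed data at
the fixed-effect SE. Specifics:

- **IVW**: origin regression; p-values and CIs normal-based; df = n−1.
  Single-SNP sets return the Wald ratio, labelled `WaldRatio` and never
  mixed into multi-SNP summaries.
- **MR-Egger**: intercept regression after orienting every (β̂_X, β̂_Y)
  pair so β̂_X > 0; df = n−2. p-values and CIs use the t distribution with
  n−2 df, matching the weighted-`lm` behaviour of the standard R
  implementations of this estimator; the IVW stays normal-based. The
  intercept p is the directional-pleiotropy test (α = 0.05).
- **Weighted median**: ratio estimates β̂_Y/β̂_X weighted by β̂_X²/σ_Y²
  (the first-order ratio variance); the 50% point of the standardized
  mid-cumulative weights is linearly interpolated. Tied ratios are
  aggregated (weights summed) before interpolation, which makes the
  estimator exactly invariant to duplicating SNPs. The SE is a seeded
  parametric bootstrap (default 1,000 draws) resampling both β̂_X and
  β̂_Y from their reported SEs; SNPs with β̂_X = 0 are dropped with a log
  entry (their ratio is undefined).
- **MR-PRESSO**: the observed statistic is the weighted residual sum of
  squares of each SNP about its leave-one-out IVW prediction. The null
  distribution comes from `n_sim` (≥ 1,000) parametric draws of (β̂_X,
  β̂_Y); per-SNP outlier p-values are each SNP's simulated-contribution
  tail probability, Bonferroni-corrected by the SNP count, flagged below
  0.05. Flagged SNPs are removed and IVW refit; "distortion" is the
  relative change of the estimate. Both the leave-one-out slopes and the
  simulated contributions are computed from running sums, so the test is
  vectorized over simulations.
- **MVMR-IVW**: weighted regression without intercept on the k exposure
  columns; df = n−k; rank-deficient exposure matrices raise an error
  naming the collinear column pairs. Conditional F-statistics (weighted
  regression of each exposure's betas on the rest) are reported as a
  weak-instrument diagnostic only — they never drop exposures — and
  ignore cross-trait sampling covariance, so they are an approximation.

Estimates are kept on the log-odds (binary outcomes) or per-SD
(quantitative) scale; report tables exponentiate to odds ratios only for
log-odds-scale rows.

## Instruments and harmonization

Selection stages, in order: significance (default p < 5×10⁻⁸; weakly
instrumented dietary traits 10⁻⁵), MAF > 0.01 and biallelic filters,
greedy LD clumping (index = smallest p, removing unclaimed variants on the
same chromosome within ±10 Mb with r² ≥ 0.001; ties broken by (p, chr,
pos, variant id) so the result is deterministic), then the per-variant
F = (β/SE)² > 10 screen. Every excluded variant is logged with its stage
and reason, and retained ∪ excluded always equals the input set.

LD pairs missing from the supplied matrix are treated as independent only
when they could not be co-clumped (different chromosome or outside the
window); a missing in-window pair raises an error rather than silently
assuming independence.

Harmonization aligns all tables to the first exposure table's effect
allele: identical pairs pass, swapped pairs flip the beta sign and EAF,
strand flips are resolved by complementing. Palindromic (A/T, C/G) pairs
cannot be strand-resolved from alleles: they are excluded as
`ambiguous_palindrome` when the minor-allele frequency exceeds 0.42 in any
table, and otherwise aligned by EAF-side agreement (effect alleles matched
so both frequencies sit on the same side of 0.5). The EAF-side rule is a
documented choice — allele codes alone cannot justify any inference for
these variants. Harmonization is idempotent.

For MVMR, instruments are the merge-before-clump union: variants passing
any exposure's own threshold, each ranked by its smallest p-value across
exposures, clumped once. Variants missing a beta in any exposure table are
dropped with a logged reason, never imputed.

## Mediation

indirect = a·b, direct = c − a·b, proportion = a·b/c, with first-order
delta-method SEs treating a, b and c as independent (they come from
separate regressions; a and c share the exposure instruments, so the
independence is an approximation — the end-to-end coverage test below
measures its practical effect). The default b is the MVMR direct effect; a
config switch substitutes the univariable estimate. Proportion CIs are
reported truncated to [0, 100]% when the point estimate lies inside, with
raw bounds always retained. A total effect within 10 SEs of zero flags the
row as unstable (`weak_total`): a ratio with a weak denominator has no
usable normal approximation. Proportions are computed for every
mediator–outcome pair and flagged `total_significant` per the rubric below.

An association is "significant" only jointly: IVW and MR-PRESSO p-values
below the family's Bonferroni threshold (0.05/7 exposure→outcomes, 0.05/5
exposure→mediators, 0.05/42 for the MVMR family — explicit configuration,
not inference), Egger and weighted-median estimates in the IVW direction,
and a non-significant Egger intercept.

## GWAS engine

Per-SNP ordinary least squares of phenotype on dosage + covariates +
intercept, including for binary outcomes (a linear probability model, as
large-biobank cancer GWAS are commonly run). Computation residualizes the
phenotype and all dosage columns on the covariate design once
(Frisch–Waugh–Lovell), which reproduces full joint OLS exactly at a
fraction of the cost; p-values use the t distribution with n−k df. SNPs
failing MAF (> 0.01) or Hardy–Weinberg (Pearson 1-df chi-square, p >
10⁻⁶; chosen over an exact test for speed and transparency) filters are
dropped with counted reasons. Because linear-probability effects on a
binary trait are not directly interpretable as odds ratios, the engine
optionally emits β/(μ(1−μ)) and SE/(μ(1−μ)) (μ = case fraction) as
log-odds-scale columns; the pipeline uses that scale for binary outcomes.
A constant phenotype yields the degenerate but well-defined OLS answer
(all betas 0, p = 1); it is an error only where it makes a computation
undefined (the log-odds conversion at μ(1−μ) = 0).

## Synthetic data generator

What it emulates: a multi-trait, two-sample summary-statistics study —
per-trait GWAS on non-overlapping cohorts, LD structure for clumping,
configurable pleiotropy, and low-prevalence binary outcomes (default case
fractions 0.4–5.7%, mirroring cancer-registry group sizes).

- **Genotypes**: Binomial(2, MAF) dosages via a Gaussian copula on two
  haplotypes; within blocks of `ld_block_size` (default 5) the latent
  normals share correlation `ld_rho` (default 0.3). The block-constant
  *latent* r matrix is what the generator supplies for clumping; the
  realized dosage correlation is attenuated relative to it (tetrachoric
  vs product-moment), which is immaterial for clumping tests since both
  sides use the supplied matrix. Hardy–Weinberg holds by construction.
- **Variance budgeting**: quantitative traits are built to unit variance
  analytically — the noise variance is 1 minus the genetic, path and
  covariate contributions (an error if the budget goes negative), then
  standardized empirically (an O(n^-1/2) correction). The configured path
  coefficients are therefore the true standardized effects, and the truth
  record's proportion mediated equals the product/total closed form
  exactly.
- **Outcome intercepts** are calibrated by Brent root finding on the mean
  predicted probability (tolerance 10⁻⁶).
- **Effect sizes**: per-SNP betas N(0, `beta_exposure_sd`²), default
  0.05, giving mean per-SNP F ≈ 25–75 at the default desk-scale sample
  sizes (30,000–50,000) — strong instruments, with a realistic fraction
  failing genome-wide significance. Defaults for the path coefficients
  are set at the magnitudes of the motivating study (a_smoking = −0.22,
  t_smoking,lower-resp = log 31.4, total lower-respiratory effect
  log 0.40, etc.), so the default DAG's implied smoking proportion
  mediated is ≈ 0.83.
- **Pleiotropy**: `balanced` adds N(0, sd) per-SNP direct exposure-SNP →
  outcome effects, `directional` adds N(sd, sd) (positive mean).
- **Two routes to summary statistics**. `two_sample=True` simulates an
  independent cohort per quantitative trait plus one shared outcome
  cohort and runs the GWAS engine — no sample overlap anywhere.
  `two_sample=False` samples β̂ ~ N(true marginal β, SE) directly with
  SE = 1/√(2·MAF·(1−MAF)·N) for quantitative traits and the same formula
  divided by √(prev·(1−prev)) for binary outcomes (the standard log-odds
  effective-sample-size approximation). True marginal effects come from
  linear path-tracing through the DAG on the log-odds scale, which
  ignores logistic non-collapsibility; at the default prevalences and
  effect sizes the attenuation is well inside the statistical noise the
  calibration suites measure. The truth record stores *structural*
  per-SNP effects; under LD the cohort route's single-SNP marginals
  additionally tag correlated neighbours, while the direct route samples
  around the structural values (post-clumping instruments are
  approximately independent either way).
- **Seeding**: one integer seed fans out through `SeedSequence` spawns,
  one child stream per trait and purpose; identical seeds reproduce
  byte-identical outputs on any platform.

What it does not emulate: realistic human LD maps, imputation
uncertainty, sex chromosomes, relatedness, population stratification that
actually correlates with genotype (the PC analogues are independent
noise), selection/"healthy volunteer" bias, or winner's-curse-free
discovery (instrument selection and estimation share each trait's single
summary table, as in the real two-sample setting). Passing tests
therefore demonstrate the statistical machinery under a correctly
specified model at desk scale, not robustness to the full messiness of
real GWAS data.

## Problem sizes

Defaults are chosen so every simulation suite runs on one CPU in minutes:
100 SNPs per trait (vs hundreds in consortium instruments), N = 30,000–
50,000 (vs 10⁵–10⁶), 1,000 bootstrap/simulation draws. Calibration suites
use 100–1,000 replicates: Egger intercept type-I error under balanced
pleiotropy (1,000 reps × 50 SNPs), IVW CI coverage without pleiotropy
(500 reps × 100 instruments at N = 50,000), MR-PRESSO outlier power (100
reps × 20 SNPs, one displaced by 10 outcome-SEs), and end-to-end recovery
of a known proportion mediated 0.80 through the full
selection→MR→MVMR→mediation chain (100 reps).

## Known limitations

- The delta method for the proportion assumes independent a, b, c and
  normality of the ratio; near-null total effects make the proportion
  ill-defined (hence the `weak_total` flag rather than a silent number).
- No correction for sample overlap between exposure and outcome GWAS is
  implemented; the generator produces non-overlapping samples, and real
  overlapping inputs would need external correction.
- Clumping requires the supplied LD matrix to cover all in-window pairs;
  there is no reference-panel computation from genotypes.
- MVMR assumes linear, homogeneous effects and no unmeasured
  mediator–outcome confounding; conditional F diagnostics flag weak
  instruments but nothing is dropped automatically.
- The linear-probability GWAS scale conversion β/(μ(1−μ)) is itself an
  approximation to the logistic log-odds; both scales are emitted so the
  choice is explicit.
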