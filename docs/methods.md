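# Methods

## Model and test statistic

The package tests H₀: no association between one variant and any of m
quantitative traits.  Traits are rotated into principal components of their
sample covariance (the n−1 denominator; PCA on the covariance, not the
correlation matrix, and traits are column-centered before projection — the
per-PC regressions carry an intercept, so centering only fixes the
convention).  Each score column is regressed by OLS on the dosage (plus
optional covariates); the Wald statistic uses the t-type standard error with
finite-sample residual degrees of freedom but is treated as standard normal,
per the asymptotics — at the sample sizes this package targets (n ≥ several
hundred) the difference is negligible.

For a contiguous grouping (m₁,…,m_K) of the eigenvalue-ordered statistics,
ξ adds −2·log χ²-survival terms per group; the grouped statistic is exactly
χ²_{2K} under the null for a *fixed* grouping, but the test maximizes over
groupings and then minimizes tail probabilities over K, so all inference
runs through resampling rather than any asymptotic form.

### Resampling null (one layer)

`build_null(m, k_max, B, seed)` draws B i.i.d. standard-normal m-vectors,
computes per-K maximal ξ values, and uses their empirical CDFs Ĥ_K both to
score observations and to score the draws themselves (each draw is a member
of the ECDF it is evaluated against, mirroring the procedure's published
description).  1 − Ĥ_K(x) is evaluated as #{draws > x}/B, so tail values are
exact permutation-style probabilities with resolution 1/B.  The null GATE
draws η⁽ᵇ⁾ are *not* uniform — the minimum of two positively correlated
empirical tails is stochastically smaller than uniform — but the final
p-value, a rank of η⁽⁰⁾ among the η⁽ᵇ⁾, is calibrated: independent null Wald
vectors give KS-uniform p-values, and the one-layer η values rank-agree with
a brute-force two-layer oracle (Spearman ρ > 0.999 at m=5, B=2000).

The published p-value formula counts η⁽ᵇ⁾ > η⁽⁰⁾; since small η is the
extreme direction, the literal count approaches 1 for overwhelming signals.
The default here counts η⁽ᵇ⁾ ≤ η⁽⁰⁾ (ties included, conservative); the
literal formula is available via `paper_formula=True`, and an optional
(r+1)/(B+1) correction avoids exact zeros.  Zero p-values are reported in
text as "< 1/B".

### Choice of K and computation

Default `k_max = 2`: with K ≥ 2 the grouped statistic has 2K "pseudo degrees
of freedom", minimized at K = 2, and larger K mainly adds computation.
General K is supported.  Maximization over groupings never enumerates
compositions: a dynamic program over group boundaries (O(K·m²) per vector,
vectorized across resampling draws) gives the exact maximum and, for
observed data, the arg-max grouping with first-in-lexicographic-order
tie-breaking.  `enumerate_compositions` (used by tests and for audit)
refuses above 10⁶ compositions unless forced.  All −2·log(1−F_d) terms are
computed with the χ² log-survival function; Wald statistics are capped at
1e8 so the terms stay finite even for numerically perfect fits.

For very small tail probabilities beyond the 1/B resolution, a maximum-
likelihood generalized-Gamma fit to −2·log η (zeros replaced by 1/(2B)) is
available (`fit_ggd_null`); it is intended for B ≥ 10⁵ and validated by
agreement of its 95% quantile with the empirical one.

### Degenerate inputs

Constant trait columns are allowed (eigenvalue 0) but their PCs carry a Wald
statistic of 0 with a warning; constant genotypes raise; collinear designs
raise.  Eigen-ties keep the decomposition's stable order — downstream
statistics are only approximately invariant to rotation within a tied
eigenspace, which is documented, not corrected.

## Comparator tests

* **FCT** Σ T_j² vs χ²_m.
* **mCPC** ξ at the (s, m−s) split with s the smallest prefix covering ≥ 80%
  of the eigenvalue sum, referred to χ²₄ (the two group sums are
  independent); s = m falls back to FCT with a warning.
* **MANOVA** additive dosage as one continuous predictor (the CCA-equivalent
  test; genotype-as-factor available).  Wilks' Λ with Rao's F, exact for
  rank ≤ 2 hypotheses; cross-checked against statsmodels MANOVA and a CCA
  oracle in the tests.
* **TATES** univariate trait p-values (vectorized OLS, two-sided t), trait
  correlations mapped to p-value correlations by the 6th-degree polynomial
  of the original publication (isolated in one constant), effective numbers
  of tests m_e(j) = j − Σ_{λ>1}(λ−1) on the reordered submatrices,
  p = min_j m_e·p₍ⱼ₎/m_e(j).
* **MultiPhen-style** proportional-odds (cumulative-logit) regression of the
  genotype on all traits, m-df LRT against the intercept-only closed form.
  The fit is an in-package Newton solver with analytic gradient and Hessian
  and step-halving (≈14 ms at m=100, n=1500), validated coefficient-for-
  coefficient against statsmodels' OrderedModel at small m; perfect
  separation and non-convergence raise a fit-failure error, and simulation
  summaries exclude and count such replicates.

## Synthetic data

The simulator is first-class and defines the study conditions.

**Genotypes** are i.i.d. Hardy–Weinberg draws at minor-allele frequency p:
(1−p)², 2p(1−p), p².  Monomorphic draws are resampled with a logged count.

**Model 1 (indirect)**: latents U_l = Gβ_l + e_l, traits Y_i = U_{⌈i/4⌉}γ_i
+ ε_i with standard-normal errors; four traits per latent share one loading.
The null trait correlation is block diagonal with entries
γᵢγⱼ/√((1+γᵢ²)(1+γⱼ²)).  **Model 2 (direct)**: one shared latent,
Y_i = Uγ_i + Gβ_i + ε_i, giving the same correlation form on all pairs.

**Structures.** S1–S4 (Model 1, m=20, loadings uniform 0.5 / uniform 2.0 /
1.0→0.2 step 0.2 / 1.5→0.7 step 0.2 across the five latents), S5–S8 the
m=100 analogues (25 latents, gradients 1−0.04(i−1) and 1.5−0.04(i−1)),
S9–S12 (Model 2, m=20: uniform 0.5, uniform 2.0, 1.00−0.05(i−1),
1.50−0.05(i−1)).  S13–S16 extend the same four patterns to m=100 with the
gradient step scaled to 0.01 so the loading range is preserved; this scaling
is the package's own convention.  The analytic correlation formula is
authoritative where rounded reference values differ in the second or third
decimal.

**Effect sizes** are solved in closed form from the per-associated-trait
explained variance h²: Model 1 β = √(h²(1+γ²)/(2p(1−p)γ²(1−h²))) per active
latent, Model 2 β = √(h²(Σγ²+1)/(2p(1−p)(1−h²))) per active trait; both
round-trip through the variance-fraction formulas to 1e−12.  A fraction λ of
traits is associated — whole latent blocks for Model 1 (a latent's effect
reaches all four of its traits, so λm must be a multiple of 4), leading
traits by default or a seeded uniform subset in `random` mode.

**Conventions**: error variances 1; n = 1500 for MAF ≤ 0.15 and n = 1000
otherwise (overridable); the nominal level is 0.05; power grids use the
per-structure h² settings of the reference study (`paper_grid`).

What the simulator does **not** emulate: linkage disequilibrium, population
structure or relatedness, non-Gaussian trait errors, binary traits, and
covariate effects.  Passing tests therefore demonstrate calibration and
relative power under clean latent-factor data, not robustness to those
real-data features.

## Simulation driver

`run_scenario` seeds replicate r from (master seed, scenario key, r) so any
replicate is reproducible in isolation and results are independent of
execution order.  One resampling null per trait count is shared across all
replicates and scenarios (the null is marker-free); B defaults to 10 000.
Monte-Carlo standard errors are √(r(1−r)/reps).

## I/O and QC

Phenotypes: TSV, sample-ID column plus named trait columns, NA/empty
missing.  Genotypes: variant-major TSV of 0/1/2/NA, or VCF (ALT-dosage from
GT, `./.` missing, multi-allelic records skipped with a warning).  QC order:
traits with missingness > 0.01, then samples with any remaining missing
phenotype, then variants with missingness > 0.15 or folded MAF < 0.05 on the
retained samples (all thresholds configurable).  Missing calls at retained
variants are mean-imputed by default so every variant is tested on the same
sample set the PCA and the shared null assume; a complete-case mode is
available and documented as changing the per-variant sample set.  Scan
output echoes the configuration and reports the Bonferroni-adjusted
threshold α / (number of variants).

## Problem sizes in the checked-in studies

The acceptance study runs the m = 20 scenarios at the reference 1000
replicates and the m = 100 scenarios at 300 replicates, with Monte-Carlo
tolerances widened accordingly; the test suite uses 200–1000 replicates per
scenario.  These sizes are the package's reproducibility defaults; all
drivers accept larger counts.

## Known limitations

* Resampling resolution is 1/B; genome-wide thresholds need B ≥ 10⁶ or the
  generalized-Gamma tail approximation.
* The proportional-odds comparator inherits MultiPhen's known type-I
  inflation at large m (reproduced, not corrected — it is part of the
  comparison).
* TATES power depends on unpublished implementation details of its original
  software; this implementation matches the Simes closed form and is
  null-calibrated, but its power under strong uniform correlation runs a few
  points above some published figures.
* No mixed-model correction: samples are assumed unrelated and unstructured.
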