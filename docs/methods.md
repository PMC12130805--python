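# Methods

This note documents the statistical model behind `mrpanel`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Two-sample MR model

All estimators operate on summary statistics: per-variant exposure
associations β̂_Xj with SE σ_Xj and outcome associations β̂_Yj with SE σ_Yj
(log-odds scale for case-control outcomes), harmonized to a common effect
allele. Under the instrumental-variable assumptions, β_Yj = θ·β_Xj for
every valid instrument, and the package's estimators differ only in how
they handle violations (direct, pleiotropic effects α_j ≠ 0):

- **IVW / GLS-IVW.** θ̂ = (β̂_Xᵀ Ω⁻¹ β̂_Y)/(β̂_Xᵀ Ω⁻¹ β̂_X) with
  Ω_jk = σ_Yj σ_Yk ρ_jk; ρ is the signed LD correlation (identity for the
  uncorrelated secondary analysis). The multiplicative random-effects SE
  multiplies the base SE (β̂_Xᵀ Ω⁻¹ β̂_X)^(−1/2) by max(1, √(RSS/(J−1))).
  The floor at 1 means residual *under*-dispersion never tightens the
  interval — the usual convention for multiplicative random-effects
  models. Exposure-side noise is ignored (the NO Measurement Error
  approximation), as in standard IVW.
- **PCA reduction for near-singular LD.** When many instruments sit in
  tight LD, Ω is numerically singular. `gls_ivw` refuses to invert any Ω
  with condition number above 10⁸ (an explicit error rather than silent
  ridge regularization, so the analyst knows the primary analysis switched
  representation). `pca_transform` eigendecomposes — without centering or
  scaling — the weighted correlation matrix
  Ψ_jk = (β̂_Xj/σ_Yj)(β̂_Xk/σ_Yk)ρ_jk, retains the smallest k whose
  cumulative eigenvalue share (eigenvalues clipped at 0, guarding against
  symmetry drift and tiny negative eigenvalues) reaches the configured
  `pca_var_explained`, and projects β̂_X, β̂_Y and Ω onto those k
  eigenvectors. Default `pca_var_explained = 0.99`: retaining 99% of the
  weighted spectrum discards only the directions responsible for the
  singularity; at 1.0 on a well-conditioned system the transformed
  estimate equals the untransformed one to numerical precision (a test
  asserts 10⁻⁸).
- **MR-Egger.** Weighted regression (weights 1/σ_Yj²) of β̂_Y on β̂_X with a
  free intercept, after orienting all β̂_X ≥ 0 (negating pairs jointly).
  The intercept estimates the mean directional pleiotropic effect under
  the InSIDE condition; inference uses the t-distribution with J−2 df and
  the same multiplicative overdispersion convention. Egger's slope is
  identified by the *dispersion* of β̂_X, so it is fragile when instrument
  effects are nearly equal — visible in the test suite, where its
  direction occasionally flips on weakly dispersed panels.
- **Weighted median.** Ratio estimates θ̂_j = β̂_Yj/β̂_Xj with first-order
  inverse-variance weights w_j = β̂_Xj²/σ_Yj²; the estimate interpolates θ̂
  at standardized cumulative weight 0.5 (s_j = (Σ_{i≤j} w_i − w_j/2)/Σw).
  Consistent while ≥50% of instrument weight is valid.
- **Mode-based estimator.** Weighted Gaussian kernel density over the θ̂_j
  evaluated on a 512-point grid spanning the θ̂ range padded by 3
  bandwidths; bandwidth φ·0.9·min(sd, IQR/1.34)·J^(−1/5) with weighted sd
  and IQR (a weighted Silverman rule, φ = 1 by default). Consistent when
  the largest homogeneous cluster of instruments is valid.
- **Bootstrap SEs.** Median and mode SEs come from a seeded parametric
  bootstrap: (β̂_Xj, β̂_Yj) resampled from normals with their reported SEs,
  1000 draws by default.
- **MR-PRESSO.** Observed RSS = Σ_j (β̂_Yj − θ̂₋j β̂_Xj)²/σ_Yj² with
  leave-one-out IVW fits θ̂₋j; the null distribution comes from parametric
  simulation of β̂_Y under the fitted model. Per-variant exceedance
  p-values are Bonferroni-corrected; variants below `alpha` are outliers,
  and the headline estimate is the outlier-corrected IVW — reported as
  absent (NA) when no outliers are found, in which case the secondary IVW
  stands. All empirical p-values use +1 smoothing ((count+1)/(n_sim+1)),
  so p = 0 is impossible; consequently the Bonferroni-corrected outlier
  test can only reject when n_sim > J/α — with the default α = 0.05 and
  J = 50 instruments this requires n_sim > 1000. The distortion p compares
  the outlier-removal shift against removals of random subsets of equal
  size (at most 500 draws).
- **Multivariable IVW.** Weighted regression of β̂_Y on the K exposure
  columns without intercept, weights 1/σ_Yj², overdispersion floor 1 with
  residual df J−K. An identically zero exposure column is excluded from
  the fit (reported with estimate 0 and infinite SE) so the remaining
  exposures reduce to the nested model; genuinely collinear designs raise.

## Harmonization conventions

Resolution order per variant: direct allele match; swapped alleles
(negate β̂_Y, complement EAF); both again after strand complementation;
palindromic pairs (A/T, C/G — their own strand complement) resolved by
effect-allele-frequency concordance unless the *exposure* EAF lies in the
configured ambiguous window [0.40, 0.60] (inclusive at both ends), in
which case the variant is dropped. The exposure side judges ambiguity
because the instrument definition lives there; records with missing EAF
can never be classified ambiguous and are dropped with a distinct
`eaf_missing` flag (conservative). Proxies (r² ≥ 0.8 against a supplied
signed LD reference) substitute outcome records for missing instruments;
the signed correlation transfers the effect direction, and ties break by
smaller exposure p-value then lexicographic ID. Clumping is greedy on
ascending p (ties lexicographic), discarding everything with r² > 0.001
to a retained index variant — deterministic and order-independent.

Thresholds r² ≥ 0.8 and r² ≤ 0.001 apply to squared correlations; the LD
matrix itself stores signed r, which the GLS estimator consumes.

## Heterogeneity and grading

Cross-subtype heterogeneity uses the closed-form DerSimonian–Laird moment
estimator (τ² = max(0, (Q − df)/(Σw − Σw²/Σw)), I² = max(0,(Q − df)/Q)·100)
rather than an iterative likelihood estimator: it is deterministic,
matches `metafor::rma(method="DL")` (cross-checked in the test suite), and
every I² = 0 conclusion (Q ≤ df) is identical across τ² estimators.
Published OR (CI) panels are converted to log-OR ± SE assuming symmetric
normal 95% intervals on the log scale; conclusions that survive CI
rounding are exactly the Q ≤ df ones, which is why only those are asserted
in tests. The evidence grade follows the four-rule scheme in README order;
an all-significant panel is graded *consistent* before direction is
examined, and log-OR values of exactly 0 are direction-neutral so that the
grade is a total function of the panel.

## Synthetic-data generator

The generator works at the summary level — the level at which every
estimator operates. Observed exposure effects are drawn jointly Gaussian
around true effects γ with covariance S·R·S (S = diag of per-variant SEs,
R = LD); outcome effects for subtype s are centred on θ_s·γ_j + α_j.
Standard errors use the large-sample approximations
se ≈ 1/√(2f(1−f)n) (quantitative) and se ≈ 1/√(2f(1−f)·n·φ(1−φ))
(case-control, case fraction φ). Defaults encode the five-subtype
breast-cancer design: 45,253 / 6,350 / 6,427 / 2,884 / 8,602 effective
cases against 91,477 shared controls, 250,000 exposure samples. EAFs are
uniform on [0.05, 0.95] except designated palindromic variants, which get
A/T or C/G pairs with EAF inside [0.40, 0.60] to exercise the
harmonization filter. Effect magnitudes are uniform on [0.4, 2.0] × 0.05
SD with random signs: every instrument clears genome-wide significance at
the default sample size while magnitudes stay dispersed, as empirical GWAS
effect-size distributions are — dispersion in β_X is what identifies the
Egger slope. Shared-control noise correlation across subtypes is a single
weight, default 0, reflecting the working assumption that control overlap
induces minimal correlation between subtype estimates; setting it > 0
mixes a common noise component at each variant. Female-specific exposure
tables scale γ by a configurable attenuation and re-noise at half the
sample size.

What the generator does **not** emulate: genotype-level sampling and
winner's curse in the discovery GWAS, the two-stage polytomous outcome
model behind real subtype GWAS (plain per-subtype logistic-scale
statistics stand in), linkage between EAF and effect size, and population
stratification. Passing tests therefore demonstrate correctness of the
pipeline arithmetic and its operating characteristics under an idealized
summary-level model, not robustness to those real-data complications.

## Problem sizes and stochastic test design

Simulation-based checks use J = 50–60 instruments and 100–1000 seeded
replicates (IVW recovery 500, type-I error 1000, PRESSO plant-and-recover
100–200, design mimicry 12 full studies), sizes at which Monte-Carlo error
is small relative to the asserted margins while the whole suite stays
desk-scale. Stochastic properties are asserted as majorities or means over
replicates rather than on a single seed: the evidence grade of a truly
null subtype is a Bernoulli outcome (each of ~6 methods carries a ~5%
false-positive chance), and the leave-one-out I² of k equal-effect
subtypes is exactly 0 only when an approximately χ²_{k−1} variate falls
below its df (probability ≈ 0.6) — single-seed assertions of such events
would test the seed, not the method. For the same reason the corrected
MR-PRESSO estimate is checked for 2-SE (95% sampling bound) coverage and
replicate-mean unbiasedness, not per-replicate 1-SE proximity, which no
calibrated estimator can deliver in 95% of replicates.

## Known limitations

- The GLS condition-number cap (10⁸) and the PCA eigenvalue clipping are
  pragmatic numerical guards, not estimators of the true LD spectrum; LD
  matrices are taken as given.
- First-order ratio-estimate variances (σ_Yj²/β̂_Xj²) underlie the median
  and mode weights; second-order corrections are not implemented.
- No multi-allelic variants, no liftover, no live LD service queries; the
  proxy search requires a user-supplied signed LD reference.
- The power approximation se(θ̂) ≈ 1/√(n·r²·φ(1−φ)) is validated against
  its own Monte-Carlo oracle, not against any external calculator.
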