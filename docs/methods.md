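# Methods

This note documents the statistical models the package implements, the
defaults and why they are set where they are, what the synthetic-data
generator does and does not emulate, and the numerical choices a
maintainer would want to know about.

## Threshold summaries

**Harrell–Davis quantiles.** For a sample of n trials the HD estimator of
the q-quantile weights the i-th order statistic by
wᵢ = I_{i/n}(a, b) − I_{(i−1)/n}(a, b), with a = (n+1)q, b = (n+1)(1−q)
and I the regularized incomplete beta function. Weights are computed by
exact beta-CDF evaluation, not the bootstrap approximation; the tests
cross-check them against direct numeric integration of the beta density to
1e−10. Detection thresholds are HD medians of the 10 change-from-baseline
values per modality (warm: T − 32; cool: 32 − T; both positive).

**Gini's mean difference.** GMD = Σ_{i≠j}|xᵢ − xⱼ| / (n(n−1)), i.e. the
mean over all *ordered* pairs excluding i = j (stated explicitly because
"all pairs" is ambiguous); computed via the O(n log n) sorted identity and
verified against brute-force enumeration. GMD is translation invariant,
so it is identical on raw temperatures and on change-from-baseline values.

**Reliability and outliers.** Block agreement uses ICC(3,2) — two-way
mixed, consistency, average of k = 2 measurements: (MS_rows − MS_err)/MS_rows
with the exact F-based CI (cross-checked against pingouin's ICC(C,k)).
Outlier flags use the classic Tukey boxplot rule with type-7
(linear-interpolation) quartiles, applied within diagnostic group; the
variant with Carling-adjusted fences was considered and not adopted, as
the classic rule is the common default and the flags feed only descriptive
output.

## Cliff's delta and equivalence testing

δ̂ is the mean of the dominance matrix d_ij = sign(xᵢ − yⱼ); ties
contribute 0. The variance is Cliff's consistent component estimator

  s² = Σᵢ(d̄ᵢ· − δ̂)²/(n₁(n₁−1)) + Σⱼ(d̄·ⱼ − δ̂)²/(n₂(n₂−1))
     + ΣΣ(d_ij − δ̂)²/(n₁n₂(n₁−1)(n₂−1)),

floored at (1 − δ̂²)/(n₁n₂ − 1), the minimum positive value recommended
when the estimator collapses near |δ̂| = 1; at exact complete dominance
|δ̂| is backed off to (n₁n₂ − 1)/(n₁n₂) for interval construction.
Confidence intervals use Cliff's asymmetric bounded transformation, which
keeps endpoints inside [−1, 1] and respects the skewed sampling
distribution near the boundary.

**TOST.** The two one-sided tests of H₀: |δ| ≥ 0.33 are carried out on the
same bounded-transform scale: the one-sided p for each hypothesis is found
by solving for the normal deviate at which the transform endpoint equals
the bound (a scalar Brent root-find), so rejection at level α coincides
exactly with the 1−2α bounded CI lying inside (−bound, bound). A plain
normal approximation on the δ scale is available (`method="delta"`), but
the transform form is the default: it is the test/CI-duality-consistent
construction, and its small-sample equivalence power matches the published
operating characteristics of this design class, which the plain form
understates at n ≲ 60. Its type-I error at the bound is slightly
conservative (≈ 0.045 at the study's sample sizes; checked by simulation).

**Monte-Carlo power.** Power simulations draw homoskedastic normal samples
whose mean shift induces the population delta via
Δ = √2·Φ⁻¹((δ+1)/2)·σ, re-estimate δ̂ and s in every replicate (no
plug-in truth), and count TOST rejections over B = 10,000 replicates.

**Categorical tests.** The 2×2 Pearson chi-square uses the closed form
N(ad − bc)²/(row·col margins) without continuity correction, with
Φ = √(χ²/N); Fisher's exact test is two-sided by hypergeometric
enumeration (scipy). Tables larger than 2×2 are out of scope.

## Rank correlations

Spearman coefficients are Pearson correlations of midranks. The Z-test
divides atanh(r_s) by the Caruso–Cliff-family standard error
√((1 + r²/2)/(n − 3)); the classical constant 1.06/(n−3) is available as
`variant="fieller"`. Equivalence TOST happens on the atanh scale against
±atanh(0.30). Correlation power simulations draw bivariate normals and
apply the full Spearman + TOST chain per replicate. Differences between
correlations use Zou's back-transformed interval; the dependent
overlapping case estimates the correlation between the two correlation
estimates with the standard overlapping-correlations formula
(Zou 2007, Eq. 20 form) and validates that the input triple is a positive
semidefinite correlation matrix.

## Cumulative probability models

The CPM treats each of the J distinct outcome values as an ordered
category and models P(Y ≥ y⁽ʲ⁾|X) = expit(αⱼ + Xβ) — continuous outcomes
are never binned. Fitting maximizes the cumulative-logit likelihood by
damped Newton iteration on the joint (α, β) parameterization, where the
log-likelihood is concave; step-halving maintains positive category
probabilities, so the ordered-intercept constraint never binds at the
optimum and no reparameterization is needed. Start values are the
closed-form intercept-only solution (empirical exceedance logits) with
β = 0; convergence is max|gradient| < 1e−8 within 100 iterations; slopes
exceeding 35 in absolute value raise a separation diagnostic. Slope
covariance comes from block inversion (Schur complement) of the observed
information. Binary outcomes reduce the model to logistic regression,
which the tests exploit as an exact oracle (1e−6 agreement), and
statsmodels' ordinal model provides an independent cross-check on
multi-category fits.

Inference: LR = 2(LL₁ − LL₀), Nagelkerke R² = (1 − e^(−LR/n))/(1 −
e^(2·LL₀/n)) against the intercept-only model, per-coefficient Wald χ²
and adjusted odds ratios e^β with 95% Wald intervals. BIC is
−2LL + k·ln(n) with k counting intercepts and slopes; since the intercept
count is fixed for a given outcome, ΔBIC across subsets depends only on
slope count. n is the subject count of the analysis sample. BIC weights
w_m ∝ exp(−ΔBIC/2) give evidence ratios and per-predictor inclusion
probabilities. The three-step hierarchy forces the baseline covariates
(diagnosis, age, sex, counterbalance order — coded ASD = 1, male = 1,
warm-first = 1) into every candidate model, consistent with all four
appearing at every step of the reported models; constant or collinear
columns are dropped with a warning rather than failing the fit.

## Multiple imputation

PMM with M = 20 by default: each imputation bootstraps the rows, fits OLS
of each incomplete covariate on the remaining numeric covariates
(mean-filling predictor gaps for prediction only), and imputes each
missing cell with the observed value of a donor drawn from the k = 3
nearest predictions. This is a deliberate simplification of
flexible-spline PMM engines: pooled Wald inference is insensitive to the
basis at these sample sizes, and imputed values remain observed donor
values either way. Outcomes (thresholds, GMDs) are never imputed. Under
imputation the best subset is chosen as the modal BIC selection across
the M completed datasets and step-3 slopes are pooled by Rubin's rules
(T = W̄ + (1 + 1/M)B); choosing the subset per-imputation versus once was
genuinely open, and the modal rule was adopted as the more stable of the
two.

## Synthetic cohort generator

The generator is the package's test bed; its defaults *are* the study
conditions.

- **Latent thresholds** are lognormal: log μᵢ ~ N(log 1.9, 0.65²) for the
  warm modality (cool offset log(2.41/1.9)), chosen so the warm median is
  ≈ 1.9 °C with IQR ≈ [1.2, 2.9] — the right-skewed shape that motivates
  HD estimation. Group separation is applied on the log scale as
  Δ = √2·Φ⁻¹((δ+1)/2)·σ_log, which by monotone invariance of δ yields the
  target delta exactly on the threshold scale.
- **Noise coupling**: trial noise SD follows
  log σᵢ = level + 1.0·log μᵢ + N(0, 0.55²). The coupling coefficient and
  spread were fixed once by a simulation sweep so the subject-level
  threshold–GMD Spearman correlation lands near 0.65–0.72 at realistic
  trial counts, and the noise level so the median GMD is ≈ 0.5 °C.
  Diagnostic-group separation in noise (default target |δ| = 0.22) shifts
  the comparison group's noise level net of the coupling pass-through.
- **Trials**: temperature = 32 ± (μᵢ + ε), ε ~ N(0, σᵢ²), clamped to the
  physically reachable span (warm within [32, 50] °C, cool within
  [0, 32] °C — the ramp moves away from baseline, and the device clamps at
  0/50). This truncation, together with the noise coupling, mechanically
  reproduces the phenomenon the analysis probes: noisier subjects get
  higher estimated thresholds.
- **Covariates**: IQ and questionnaire scores are normals with
  delta-calibrated group shifts (IQ targets live in the same target map as
  questionnaire targets); the SRS-2 sensory item is a clipped normal on
  [0, 3], so its empirical delta undershoots its nominal target (tie mass
  at the floor) — delta-recovery checks therefore use unclipped variables.
  PIQ and sex effects on thresholds are additive in °C (defaults
  −0.01 °C/point and +0.3 °C male−female), applied after the lognormal
  draw and floored at 0.05 °C. The joint covariate distribution (e.g. any
  PIQ–sex association) is not modeled beyond these effects, since no
  target values exist for it.
- **Missingness** is MCAR at per-variable rates matched to the observed
  covariate Ns (IQ ≈ 3%, SRS-2 ≈ 20–22%, sensory profiles 13–20%, ADOS
  13%); the true missingness mechanism of such studies is unknown, and
  MCAR is the assumption under which the imputation recovery tests are
  meaningful. Identity and design columns can never be made missing.
- **Determinism**: one integer seed drives subject, trial and missingness
  generation through independent child streams; equal seeds give
  bit-identical tables.

What the generator does *not* emulate: reaction-time dependence of the
stopping rule (thresholds here are noise-plus-latent constructs, not
drift–diffusion outcomes), medication effects, correlated questionnaire
batteries, or non-MCAR missingness. Passing tests therefore demonstrate
that the estimators and tests behave correctly under the assumed
data-generating structure — not that the structure itself is the true
physiology of thermal detection.

## Problem sizes used in the test and acceptance runs

Monte-Carlo powers use the full B = 10,000; the TOST type-I check uses
5,000 replicates; CPM Wald coverage uses 1,000 datasets of n = 300;
delta-recovery checks use 500 subjects per group; Zou coverage checks use
1,000–1,500 replicates. These sizes put Monte-Carlo error comfortably
inside each test's tolerance while keeping the whole suite in the
low minutes on a single core.

## Known limitations

- The TOST's transform-scale construction is mildly conservative at the
  equivalence bound (size ≈ 0.045 rather than 0.050 at n ≈ 60–140).
- The CPM does not implement probit/loglog links, penalization, or
  censoring; exact small-n Spearman tables and permutation nulls for δ are
  out of scope.
- PMM here is single-pass (not chained equations); with several jointly
  missing covariates its between-variable consistency is approximate.
- With heavy ties the delta CI's boundary back-off is a convention, not an
  exact small-sample interval.
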