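# Methods

## Setting and model

`twosmr` implements two-sample Mendelian randomization at the
summary-statistic level. The working model: independent, LD-clumped
SNPs j = 1..J affect the exposure X with effects γ_j; the outcome Y
satisfies, on the per-allele scale,

    β_Yj = θ · γ_j + α_j,

where θ is the causal effect of interest and α_j is SNP j's direct
(pleiotropic) effect on the outcome. Valid instruments have α_j = 0.
Observed summary statistics are the GWAS estimates β̂_Xj, β̂_Yj with
standard errors, assumed Normal around the true effects and independent
between the two samples (non-overlapping GWAS cohorts). Both traits
here are binary, so effects are log-odds per allele and the causal
estimate is a log-odds ratio of outcome per log-odds of exposure.

The packaged exposure instrument set is the 102-SNP table for major
depressive disorder from a European-ancestry meta-analysis of 807,553
individuals (genome-wide significant, clumped to independence). The
table ships verbatim, including its printed per-SNP R² and F columns
(`r2_printed`, `f_printed`). The printed R² column is internally
inconsistent with the R² formula below (e.g. for rs301799 the formula
gives 3.07e−4 while the table prints 1.08e−3), whereas the printed F
column matches the formula; the raw columns are therefore kept for
reference only and every computation uses the formula.

## Harmonization

Outcome records are aligned to the exposure's effect allele by direct
match, effect/other swap (negate β_Y, reflect EAF), strand complement,
or complement-plus-swap; anything else is an `allele_mismatch`.
Palindromic SNPs (A/T, C/G) are identical on both strands, so strand
cannot be inferred from alleles; they are excluded as
`palindromic_ambiguous` when the EAF falls within the ambiguity window
[0.5 − w, 0.5 + w], and otherwise taken at face value — no
frequency-based strand inference is attempted, matching the practice of
dropping rather than guessing.

* **Window default w = 0.08** ([0.42, 0.58], boundary inclusive). On the
  packaged table the six excluded palindromic instruments have exposure
  EAF in [0.4534, 0.5438] and all seven retained palindromic SNPs fall
  outside [0.42, 0.58], so this window reproduces the study's exclusion
  set exactly and with margin on both sides.
* **Both sides checked by default**: a palindromic SNP is ambiguous if
  either the exposure or the outcome EAF is in the window
  (`palindromic_check="exposure"` restricts to the exposure side; the
  choice is immaterial for the packaged set).
* Proxy substitution is an interface only: the harmonizer accepts a
  caller-supplied `{snp: proxy_snp}` mapping; LD lookup against a
  reference panel is out of scope.

The exclusion log records every dropped SNP with its reason, so
`len(pairs) + len(exclusions)` always equals the instrument count. On
the packaged table against the breast-cancer outcome data this is
102 = 92 + 4 (missing) + 6 (ambiguous palindromes).

## Instrument strength and power

Per-SNP variance explained uses R² = 2·EAF·(1−EAF)·β², and instrument
strength F = R²(n−1−k)/((1−R²)k). Per-SNP F values use k = 1 (each SNP
as its own instrument — the convention under which the packaged table's
printed F column is reproduced within 0.5%, the slack being rounding of
the printed 4-dp inputs); k is exposed for aggregate F. The aggregate
R² of the 92 retained instruments is 2.448%.

Binary-outcome power uses the noncentral-χ² approximation: with total
sample N, case fraction K, and expected odds ratio OR per unit of
exposure, b = K(OR/(1 + K(OR−1)) − 1), v = K(1−K) − b²,
NCP = N·R²·b²/v, and power = P(χ²₁(NCP) > χ²₁ critical at 1−α). This
is the calculation used by the mRnd web tool; it reproduces all three
published power values for this design (≥0.80 at OR 1.090 overall,
0.46 at OR 1.059 for ER+, 0.55 at OR 1.101 for ER−), which validates
the reconstruction. At OR = 1 the NCP is 0 and power equals α exactly.

## Estimators

* **Wald ratio**: θ̂_j = β̂_Yj/β̂_Xj with first-order delta SE
  σ_Yj/|β̂_Xj| by default. The second-order SE (adding the
  exposure-side term) is available via `se_mode="delta2"`; first-order
  is the default because it is the dominant convention and the packaged
  instruments are strong (F ≥ 147), making the correction negligible.
* **IVW**: inverse-variance-weighted mean of the ratios, identical to
  weighted least squares of β̂_Y on β̂_X through the origin with
  weights 1/σ_Y². "IVW" unqualified means the multiplicative
  random-effects variant (SE × max(1, √(Q/(J−1)))), the convention of
  the standard MR toolchain; `ivw_fixed` is the plain fixed-effects
  mode. Both share the point estimate; inference is normal-based.
  Cochran's Q with J−1 df is returned alongside.
* **Weighted median**: ratios sorted ascending; with normalized weights
  the centered cumulative weight s_j = (Σ_{i≤j} w_i − w_j/2)/Σw is a
  piecewise-linear quantile function, and the estimate interpolates it
  at 0.5. The point estimate is deterministic; the SE is a parametric
  bootstrap (θ*_j ~ N(θ̂_j, se_j²), default 1000 reps, seeded). Note
  the interpolated definition is exactly invariant to input order, and
  to splitting points in half *at equal weights*; under strongly unequal
  weights splitting changes the interpolation knots and can move the
  estimate, so no such invariance is claimed or tested there.
* **MR-Egger**: pairs oriented so β̂_Xj > 0 (both betas negated as
  needed — the fit is invariant to reported-allele choice), then
  weighted regression with intercept, weights 1/σ_Y². SEs carry a
  multiplicative overdispersion factor max(1, σ̂) with
  σ̂² = weighted RSS/(J−2); inference uses t with J−2 df. The slope is
  the causal estimate under InSIDE (pleiotropy independent of
  instrument strength); the intercept estimates mean directional
  pleiotropy. Plain weighted regression, no simulation-extrapolation.
* **MVMR**: weighted least squares of β̂_Y on the J×E matrix of
  exposure effects without intercept, weights 1/σ_Y²; per-exposure
  coefficient, SE and normal p. The same overdispersion floor
  max(1, σ̂²) with J−E df scales the covariance, consistent with the
  random-effects IVW convention (with E = 1 the coefficient equals the
  fixed-effects IVW estimate exactly). Rank deficiency is detected by
  pivoted QR on the weighted design and reported with the offending
  column names. Assembly of the instrument set across exposures
  (union/intersection, cross-trait LD pruning) is the caller's job: the
  operation consumes an already-harmonized matrix, because constructing
  it requires external confounder GWAS data and LD panels.

Bonferroni reporting: with m = 3 outcomes, p < α/m ≈ 0.017 is labelled
`strong`, α/m ≤ p < α `suggestive`, otherwise `ns`.

## Diagnostics

* **Leave-one-out**: IVW re-fit dropping each SNP, plus a full-set
  reference row.
* **MR-PRESSO**: observed statistic RSS = Σ_j w_j(β̂_Yj − θ̂_{−j}β̂_Xj)²
  with θ̂_{−j} the leave-one-out through-origin slope and w_j = 1/σ_Yj².
  The null is simulated parametrically: β*_Xj ~ N(β̂_Xj, σ_Xj²),
  β*_Yj ~ N(θ̂_{−j}β̂_Xj, σ_Yj²), leave-one-out slopes recomputed per
  replicate. The global p is the fraction of simulated RSS at or above
  the observed; per-SNP outlier p-values come from each SNP's simulated
  residual² distribution, Bonferroni-corrected over J, flagged below
  0.05. The corrected estimate is the random-effects IVW on the
  survivors. The distortion p compares the raw-vs-corrected shift
  against the shift from removing equally many SNPs at random (without
  replacement), a simulation analogue of the original test; it is
  reported but never used for gating — corrected estimates are reported
  unconditionally. Default 1000 replicates, seeded, bit-reproducible;
  the global p has Monte-Carlo SE ≤ √(p(1−p)/reps). The global test is
  well calibrated at J ≳ 20 and conservative for very small sets
  (rejection ~1% at J = 8 in the package's own simulations).
* **Steiger directionality**: exposure-side R² is Σ 2·EAF(1−EAF)β̂_X²;
  for a binary outcome the per-SNP variance explained is recovered from
  the association z-statistic as z²/(z² + n), which needs no outcome
  frequency or prevalence input (a liability-scale conversion would;
  it is noted, not implemented — `case_fraction` is accepted for
  interface symmetry and unused). The verdict is direction_ok iff
  R²_exposure > R²_outcome (strict), and the p-value compares Fisher
  z-transforms of the two correlation magnitudes with a two-sample
  normal test, so identical R² on both sides gives p = 1. The verdict
  is invariant to negating all betas.
* **Plot data**: funnel (ratio vs precision), scatter (effect pairs
  plus per-method fitted lines — IVW and median through the origin,
  Egger with its fitted intercept), and forest (per-SNP Wald CIs plus
  one summary row per estimate) as plain tables; no figure rendering
  in the core.

## Synthetic data generator

`simulate_two_sample` draws truth and observations at the summary
level: EAF ~ U(0.10, 0.95); γ_j = ±|U(0.02, 0.05)| with random sign
(the magnitude range of the packaged instrument table); exposure SE
1/√(2·EAF(1−EAF)·n_exp); outcome SE 1/√(2·EAF(1−EAF)·n_out·K(1−K))
with case fraction K; β̂ ~ N(truth, SE²). Defaults are the study
conditions: J = 92, n_exp = 807,553, n_out = 228,951, K = 0.537, and
causal effect 0.0834 log-odds (OR 1.087). Pleiotropy modes: `none`;
`balanced` α ~ N(0, sd²); `directional` α = sign(γ)·N(μ, sd²) — defined
relative to the exposure-increasing allele, since pleiotropy applied in
the reported-allele frame cancels under random effect signs and would
be undetectable by construction; and `planted_outliers`, offsets of
10× the outcome SE on chosen SNPs (optionally sign-randomized via
`outlier_random_sign` to model corruption with no net direction).
Defaults μ = sd = 0.005 put mean pleiotropy at ~15% of a typical ratio,
large enough to bias IVW by several standard errors yet small enough
that Egger remains stable. A configurable fraction of SNPs gets
palindromic alleles and a configurable fraction of outcome records
arrives allele-swapped, exercising the harmonization path; by default
no palindromes are generated so a run yields exactly J analyzable
pairs, the post-validation regime the estimators assume.

`simulate_study_like` reuses the packaged table verbatim as the
observed exposure GWAS (preserving its EAFs, alleles, effect sizes and
hence the printed F range), simulates only the outcome side around a
causal effect of 0.0834, withholds the same four SNPs the real outcome
data lack, and allele-swaps a quarter of the rest — so harmonization
reproduces the 102 → 92 reduction end to end with known truth.

What the generator deliberately does **not** emulate: LD between
instruments (they are post-clumping by assumption), winner's-curse bias
in instrument selection, sample overlap between the two GWAS, liability-
scale attenuation of binary-trait effects, population stratification,
and EAF discrepancies between studies. Passing tests therefore show the
estimators behave correctly *given* valid summary statistics from
non-overlapping samples; they do not certify robustness to those
upstream artifacts.

## Test regimes and numerical choices

Statistical guarantees are checked at fixed seeds chosen a priori:

* Estimator recovery and IVW type-I error: 500 replicates at the study
  scale (J = 92); means compared to truth within 2 Monte-Carlo SEs, the
  rejection rate to the binomial 95% band around 0.05.
* Egger/IVW separation under directional pleiotropy: 500 replicates;
  the Egger intercept must recover μ within 2 MC-SEs while the IVW bias
  exceeds 10 MC-SEs.
* PRESSO outlier recovery uses 5 instruments. With J strong instruments
  the raw-minus-corrected shift from a single 10×SE outlier scales as
  1/J while the corrected estimator's own SD scales as 1/√J, so
  "removal beats noise ≥95% of the time" holds only for compact sets
  (roughly J ≤ 9); at J = 92 a single such outlier moves the pooled
  estimate by only a third of its SE and removal wins merely ~70% of
  the time. The compact set is the regime the recovery property is
  about; the planted outlier is still flagged essentially always at
  either scale.
* PRESSO null calibration is checked at J = 20 (200 replicates, 300
  simulations each), inside the well-calibrated regime noted above.

Numerical conventions: normal-based CIs and p-values everywhere except
MR-Egger (t, J−2 df); SE floors never deflate below fixed-effects;
simulation p-values are plain exceedance fractions, so a global p of 0
means "below 1/reps"; the weighted-median bootstrap and all PRESSO
simulations take explicit seeds and are bit-reproducible; report TSVs
serialize floats at 17 significant digits and files are re-read with
round-trip float parsing, making write→read lossless; monomorphic SNPs
(EAF 0 or 1) have R² = 0 by construction; a single-pair IVW degenerates
to the Wald ratio with a warning.

## Known limitations

* No LD handling anywhere: clumping, proxy discovery, and cross-trait
  LD pruning all happen upstream, and the harmonizer's proxy hook
  trusts the caller's LD evidence.
* The z²/(z² + n) Steiger recovery treats the binary-outcome z-statistic
  as a correlation signal; it is an approximation, and exposure- and
  outcome-side R² are computed on different scales (formula vs
  z-recovery), which is the standard but not a perfectly symmetric
  comparison.
* MR-PRESSO's distortion test differs in resampling detail from the
  original formulation (random subsets without replacement rather than
  bootstrap re-selection); it is reported for orientation only.
* The power approximation ignores instrument-strength uncertainty and
  assumes the aggregate R² is known.
* Estimates for binary exposures carry the usual caveat that a log-odds
  "unit" of liability is not a clinical exposure dose; effect sizes are
  interpretable comparatively, not as intervention effects.
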