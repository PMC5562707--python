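# Methods

## The two-sample summary-data model

For each instrument SNP *j*, two independent GWAS provide the estimated
per-allele association with the exposure, γ̂ⱼ ~ N(γⱼ, σ²_Xⱼ), and with the
outcome, Γ̂ⱼ ~ N(Γⱼ, σ²_Yⱼ). Under a linear causal model with effect β and
a possible direct (pleiotropic) effect αⱼ of the variant on the outcome,

    Γⱼ = β·γⱼ + αⱼ .

A variant is a *valid* instrument when αⱼ = 0. All estimators in the
package assume the two samples are non-overlapping (sampling errors of
γ̂ⱼ and Γ̂ⱼ independent) and instruments mutually independent (LD-pruned).
Before estimation, panels are harmonized: exposure and outcome estimates
are expressed on the same allele and oriented so that every γ̂ⱼ > 0.

### Estimators

* **IVW** — β̂ = Σwⱼγ̂ⱼΓ̂ⱼ / Σwⱼγ̂ⱼ², wⱼ = σ_Yⱼ⁻². Fixed-effect SE
  (Σwⱼγ̂ⱼ²)^(−1/2); optionally inflated by max(1, √(Q/(k−1))) with
  Cochran's Q (multiplicative random effects). Fixed-effect is the
  default: it matches the originally proposed summary-data combination
  the package reproduces, and Q-based heterogeneity handling is exposed
  separately through the stepwise filter. Normal inference,
  95% CI multiplier z₀.₉₇₅ = 1.959964.
* **MR-Egger** — weighted least squares of Γ̂ on γ̂ *with* intercept,
  weights σ_Yⱼ⁻². The intercept estimates the mean directional
  pleiotropic effect; the slope is consistent for β under InSIDE
  (instrument strength independent of direct effects). SEs use the WLS
  covariance scaled by max(1, residual dispersion); inference uses
  t(k−2). The t-based choice is conservative for small panels; it affects
  p-values and CI widths only, never point estimates.
* **Weighted median** — per-SNP ratios β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SEs
  σ_Yⱼ/|γ̂ⱼ| (exposure-side uncertainty is assessed separately via NOME
  diagnostics); ratios sorted, weights wⱼ ∝ SEⱼ⁻² normalized, cumulative
  midpoints pⱼ = Sⱼ − wⱼ/2, estimate = linear interpolation at p = 1/2.
  SE by parametric bootstrap: γ̂ⱼ and Γ̂ⱼ resampled from normals at their
  estimates, default 10,000 replicates, seed required for
  reproducibility. Consistent while valid instruments carry at least half
  the weight.
* **Multivariable IVW** — Γ̂ regressed on the instrument associations
  with m exposures jointly (no intercept, weights σ_Yⱼ⁻²), t(k−m)
  inference with dispersion-scaled SEs. An exposure column that is
  identically zero is handled by the pseudo-inverse (zero coefficient),
  which makes the single-exposure reduction exact; genuinely collinear
  nonzero exposures raise an error naming the offending traits.
* **I²_GX** — with uⱼ = σ_Xⱼ⁻² and weighted mean γ̄:
  Q_GX = Σuⱼ(γ̂ⱼ−γ̄)², I²_GX = max(0, (Q_GX−(k−1))/Q_GX). Values near 1
  mean the no-measurement-error (NOME) assumption holds for the Egger
  regression; 1 − I²_GX approximates the relative attenuation of the
  Egger slope (verified in the tests to within ±0.05 at k = 100 under
  moderate error).
* **SIMEX-corrected Egger** — for each λ in {0.5, 1, 1.5, 2}, the
  exposure betas are perturbed n_sim = 1,000 times (tests and the
  acceptance script use 200, which leaves the per-λ mean slope
  Monte-Carlo error far below the correction size) with
  N(0, λσ²_Xⱼ) noise, Egger slopes averaged per λ, and a quadratic in λ
  (anchored at the unperturbed λ = 0 fit) extrapolated to λ = −1. The SE
  uses the standard SIMEX variance construction (mean sampling variance
  minus between-simulation variance, extrapolated the same way, floored
  at the smallest positive grid value when the extrapolation turns
  negative) and is reported as approximate. A quadratic extrapolant over
  a grid reaching λ = 2 is the standard configuration; shrinking the grid
  toward 0 makes the extrapolation to −1 noise-dominated, so narrow grids
  are not recommended (the corrected estimate converges to the naive one
  as σ_X → 0, and exactly equals it at σ_X = 0).

### Instrument quality control

* **Explained variance** R² = Σᵢ βᵢ²·2·MAFᵢ(1−MAFᵢ)/var(X), var(X) = 1
  for traits analysed in SD units. Requires allele frequencies; SNPs
  without eaf are excluded from this computation by design.
* **Cross-trait exclusion** removes instruments appearing in (or in LD
  r² strictly > 0.8 with) other traits' instrument lists; the check can
  be restricted to a named subset of lists (e.g. non-lipid traits only,
  to preserve power when lipid instrument sets overlap heavily).
* **Stepwise Q filter**: fit IVW, Q = Σwⱼ(Γ̂ⱼ−β̂γ̂ⱼ)² against χ²(k−1);
  while p < 0.05, remove the SNP with the largest individual contribution
  wⱼ(Γ̂ⱼ−β̂γ̂ⱼ)² (ties broken by smaller rsid for deterministic runs),
  refit, repeat; stop at homogeneity or at a floor of 2 SNPs (flagged,
  not an error). Removal by largest contribution was verified equivalent
  to exhaustive leave-one-out on test panels. The per-variant F statistic
  cannot be computed from summary data; restricting instruments to
  genome-wide-significant, independent SNPs implies F > 30 per variant,
  which the package logs as a heuristic.

### Power

On standardized scales the IVW estimator of β is approximately
N(β, 1/(n_outcome·R²_GX)) — the outcome sample drives the variance, so
n is the outcome-dataset size. Detectable effect at two-sided level α and
power 1−κ: β_det = (z₁₋α/₂ + z₁₋κ)/√(n·R²_GX); since β² equals the
outcome variance explained by the exposure on these scales, β²_det is
reported as the detectable explained variance. Defaults α = 0.05/8 =
0.00625 (four correlated trait blocks, both directions) and power 80%
reproduce the published design analysis for outcome samples of
13,813–322,206 with instrument R² between 0.6% and 7.3%. One published
cell (fasting glucose in the reverse direction) is internally
inconsistent with its printed inputs (stated instrument R² 2.90% implies
a detectable 0.33%, not the printed 0.48%) and is excluded from the
checks.

## Harmonization rules

Matching is by rsid only (genomic positions are metadata). Outcome
alleles are matched to exposure alleles directly, order-swapped (sign
flip, eaf complement), or strand-complemented. Palindromic (A/T, C/G)
SNPs are strand-ambiguous: they are kept only when both datasets provide
allele frequencies outside [0.42, 0.58], in which case frequency
discordance across datasets implies a strand flip; otherwise they are
dropped with a note. This frequency-window rule is the conservative
community default; the consortium analyses the package reproduces do not
state theirs. After alignment, records with γ̂ < 0 are re-oriented
(both betas negated, alleles swapped, eaf complemented) and γ̂ = 0
records dropped, so harmonization is idempotent and sign-convention
invariant.

## The synthetic-data generator

`generate_two_sample_panel` draws, per SNP: MAF ~ U(0.1, 0.5); true
γⱼ ~ N(0.3, 0.15²) truncated positive; αⱼ = 0 for valid SNPs and
N(α_mean, α_sd²) (directional; α_mean forced to 0 in balanced mode) for
the round(invalid_fraction·k) invalid ones, independently of γ (InSIDE
holds by construction); Γⱼ = β·γⱼ + αⱼ; standard errors
σ = 1/√(2n·MAF(1−MAF)) (the standardized per-SNP regression SE under
Hardy–Weinberg); observed estimates with independent noise in the two
samples. Panels are returned pre-harmonized; when sampling noise flips an
observed exposure sign the record is re-oriented exactly as harmonization
would (and the truth record flipped with it). Defaults: k = 50,
n = 50,000 in both samples, β = 0.1, α_mean = 0.02, α_sd = 0.01, one
global seed from which all derived analyses spawn child streams.

Design of the defaults. The SNP-exposure effect scale (mean 0.3 SD,
sd 0.15, truncated positive) places the generator deep in the
strong-instrument regime: per-variant F ≈ (γ/σ_X)² in the hundreds to
thousands and I²_GX ≈ 0.998 at the default sample sizes. This is
deliberate: the Monte-Carlo validation asserts finite-sample
unbiasedness of IVW, the Egger slope, and the weighted median at a
precision of a few 10⁻⁴ (3 Monte-Carlo SEs over 1,000 replicates), and
the Egger slope carries a regression-dilution bias of order
(1 − I²_GX)·β that would dominate at realistic per-SNP effect sizes.
Two further consequences of weaker settings were measured and motivated
this choice: with γ mass near zero, re-orientation of noise-flipped SNPs
correlates the flipped pleiotropic effects with instrument strength
(breaking InSIDE and biasing the Egger slope under directional
pleiotropy), and the NOME attenuation alone shifts the Egger slope by
several Monte-Carlo SEs. Measurement-error behaviour is studied
separately by shrinking the exposure sample (n_exposure = 350 with
k = 100 yields I²_GX ≈ 0.7).

What the generator does *not* emulate: LD between instruments (real
panels are pruned to r² < 0.1), sample overlap between the exposure and
outcome GWAS (the consortia analysed overlap by 19–80%, biasing
estimates toward the observational association — no summary-level
correction exists), winner's-curse selection of instruments, allele
miscoding/strand errors (exercised separately through harmonization
fixtures), and non-normal effect distributions. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to these real-data features.

`generate_multivariable_panel` mixes latent per-exposure effects through
a loadings matrix to create instruments shared between correlated
exposures; the outcome is built from a causal vector. At off-diagonal
loadings near 1 the exposure-beta matrix becomes nearly collinear and
exposure measurement error biases even the multivariable model (measured
bias ≈ 0.07 at loading 0.9); the validation uses loading 0.5, where the
univariable estimate is strongly confounded (bias ≈ 0.2) and the
multivariable estimate recovers the truth to well under 2%.

## Monte-Carlo validation (what the tests compute)

Scenario sizes were chosen to keep the full suite under a minute of
simulation time while leaving Monte-Carlo error well below the effects
being detected.

* *No pleiotropy* (k = 50, n = 50k/50k, β = 0.1, 1,000 replicates): mean
  bias of IVW, Egger slope, and weighted median each within 3 MC SEs.
* *Directional pleiotropy, 100% invalid, InSIDE* (α_mean = 0.02): Egger
  slope unbiased within 3 MC SEs while IVW bias exceeds 5 MC SEs (the
  IVW estimand shifts by E[α]·E[wγ]/E[wγ²] ≈ 0.05). The Egger intercept
  recovers α_mean up to a small coupling with the residual NOME
  attenuation (bounded at 4 MC SEs in the generator tests).
* *Balanced pleiotropy, 30% invalid*: weighted median unbiased within
  3 MC SEs. Under *directional* 30% invalidity the weighted median is
  consistent but not finite-sample unbiased — the invalid mass shifts the
  weighted quantile by an amount proportional to the per-SNP ratio
  spread, which no sample size removes at fixed precision — so the
  directional case is validated as a contrast instead: weighted-median
  distortion under 30% directional invalidity is less than half the IVW
  distortion, and at 70% invalidity (majority-invalid negative control)
  it breaks down.
* *NOME/SIMEX* (k = 100, n_exposure = 350 → I²_GX ≈ 0.7,
  200 replicates): the SIMEX-corrected slope is closer to the truth than
  the naive slope in ≥ 80% of panels; I²_GX is monotone decreasing under
  σ_X inflation.
* *Heterogeneity filter*: a 21-SNP panel with one outcome estimate offset
  by 10σ_Y has exactly that SNP removed, and the filter terminates with
  final p ≥ 0.05; homogeneous panels are untouched.

## Numerical choices and degenerate inputs

WLS solves use the pseudo-inverse of the weighted normal equations.
Bootstrap resamples that land exactly on γ̂ = 0 are nudged to the
smallest positive float before forming ratios. A fully degenerate
weighted-median bootstrap (zero spread) reports the smallest positive
float as SE rather than zero, keeping downstream CI/p-value arithmetic
defined. Cochran's Q p-values use the survival function of χ²(k−1);
Q = 0 panels report I²_GX = 0 by the max(0, ·) truncation. Ties in the
Q-filter removal step are broken by lexicographically smaller rsid so
runs are deterministic. All stochastic components (bootstrap, SIMEX,
generator) take explicit seeds; the pipeline derives per-method child
seeds from the plan seed via CRC-tagged seed sequences, making report
files byte-identical across reruns.

## Known limitations

* The SIMEX SE is an approximation (extrapolated variance components);
  the point estimate is the quantity of record.
* Binary outcomes are not modelled (all traits in the reproduced design
  are continuous).
* The sample-overlap bias between consortia is acknowledged but not
  modelled, matching the scope of the analysis the package reproduces.
* LD is consumed from precomputed tables, never estimated from genotype
  reference panels.
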