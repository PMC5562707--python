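# mrlink

Bidirectional two-sample Mendelian randomization (MR) from GWAS summary
statistics.

MR uses genetic variants as instrumental variables to ask whether an
observed association between two traits — say, triglyceride levels and a
circulating apolipoprotein — reflects a causal effect rather than
confounding or reverse causation. In the *two-sample* setting the per-SNP
associations with the exposure (γ̂ⱼ, SE σ_Xⱼ) and with the outcome (Γ̂ⱼ,
SE σ_Yⱼ) come from different GWAS consortia and are combined at summary
level. `mrlink` is for analysts who have such summary tables and want the
full analysis chain: harmonization, instrument quality control, the
standard estimators with their sensitivity analyses, design/power
calculations, and a ground-truth simulator to validate every step.

## What it computes

* **Harmonization** (`mrlink.summary_data`) — joins exposure and outcome
  tables on rsid, re-expresses the outcome estimate on the exposure's
  effect allele (handling swapped alleles and strand flips; palindromic
  A/T–C/G SNPs are resolved by allele frequency or dropped), and orients
  every record so γⱼ > 0.
* **IVW** (`mrlink.ivw_estimate`) — the inverse-variance weighted
  estimate β̂ = Σwⱼγⱼ Γⱼ / Σwⱼγⱼ², wⱼ = σ_Yⱼ⁻², i.e. weighted regression
  of Γ̂ on γ̂ through the origin; fixed-effect SE (Σwⱼγⱼ²)^(−1/2), with an
  optional multiplicative random-effects inflation √(Q/(k−1)).
* **MR-Egger** (`mrlink.egger_estimate`) — the same weighted regression
  *with* an intercept; the intercept estimates directional pleiotropy,
  the slope remains a consistent causal estimate under the InSIDE
  assumption.
* **Weighted median** (`mrlink.weighted_median_estimate`) — the median of
  the per-SNP Wald ratios Γ̂ⱼ/γ̂ⱼ under inverse-variance weights,
  consistent while valid instruments carry ≥ 50% of the weight;
  parametric-bootstrap SE.
* **Multivariable IVW** (`mrlink.multivariable_ivw_estimate`) — Γ̂
  regressed on several exposures' genetic associations simultaneously,
  for correlated exposures with overlapping instruments (e.g. the lipid
  fractions).
* **NOME diagnostics** (`mrlink.i2_gx`, `mrlink.simex_egger`) — I²_GX
  quantifies measurement error in the SNP-exposure estimates (1 − I²_GX
  ≈ relative attenuation of the Egger slope); SIMEX re-estimates the
  slope under inflated exposure noise and extrapolates back to the
  no-error point λ = −1.
* **Instrument QC** (`mrlink.instrument_qc`) — explained variance
  R² = Σβᵢ²·2·MAFᵢ(1−MAFᵢ)/var(X); exclusion of instruments overlapping
  (or in LD r² > 0.8 with) other traits' instrument sets; the stepwise
  Cochran-Q heterogeneity filter that removes the largest Q contributor
  until the panel is homogeneous.
* **Power** (`mrlink.power`) — the detectable causal explained variance
  β²_det with β_det = (z₁₋α/₂ + z_pow)/√(n·R²_GX), and power at a given
  effect.
* **Simulator** (`mrlink.simulate`) — two-sample panels with known causal
  effect, balanced/directional pleiotropy satisfying InSIDE, and an
  invalid-instrument fraction.

The estimators are scikit-learn-style classes (`IVWEstimator`,
`EggerRegression`, `WeightedMedianEstimator`, `MultivariableIVW`,
`SimexEgger`) with `fit(X, y, y_se=..., x_se=...)` and fitted attributes
(`beta_`, `se_`, `ci_`, `pvalue_`, ...); the functions above are thin
wrappers over them.

## Worked example

```python
from mrlink import (SimPanelConfig, generate_two_sample_panel,
                    ivw_estimate, egger_estimate, weighted_median_estimate,
                    i2_gx_panel)

cfg = SimPanelConfig(k=50, beta_causal=0.1, pleiotropy_mode="directional",
                     invalid_fraction=0.3, seed=7)
panel, truth = generate_two_sample_panel(cfg)

ivw = ivw_estimate(panel)
egger = egger_estimate(panel)
wm = weighted_median_estimate(panel, n_boot=2000, seed=7)
print(f"IVW    beta={ivw.beta:.4f}  95% CI [{ivw.ci_low:.4f}, {ivw.ci_high:.4f}]")
print(f"Egger  beta={egger.beta:.4f}  intercept={egger.intercept:.4f} "
      f"(p={egger.intercept_p:.3f})")
print(f"WMed   beta={wm.beta:.4f}")
print(f"I2_GX = {i2_gx_panel(panel):.3f}")
```

prints

```
IVW    beta=0.1121  95% CI [0.1061, 0.1181]
Egger  beta=0.1008  intercept=0.0041 (p=0.320)
WMed   beta=0.1071
I2_GX = 0.997
```

Read: 30% of the 50 instruments carry a directional pleiotropic effect
(mean 0.02), so the IVW estimate (0.112) overshoots the true causal
effect of 0.1 — its CI excludes the truth; the Egger slope (0.101) is
close to the truth, its positive intercept pointing the right way though
a single 50-SNP panel gives it little power; the weighted median sits in
between; I²_GX ≈ 1 says measurement error in the SNP-exposure estimates
is negligible here.

From the shell, the same machinery is available as

```sh
mrlink simulate --config generator.yaml --out panel --truth truth.tsv
mrlink run --config plan.yaml --out report.tsv --log run.log
mrlink power --alpha 0.00625 --power 0.8 --n-outcome 13813 --r2-gx 0.0676
```

where `plan.yaml` names the exposure/outcome tables for each pair, the
methods to run, sensitivity options (heterogeneity filter, named SNP
exclusions, cross-trait/LD exclusion), the significance threshold
(default 0.05/8 = 0.00625 for four correlated trait blocks tested in two
directions), and the seed. The report has one TSV row per
(exposure, outcome, method), both directions of every pair.

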