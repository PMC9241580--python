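# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics, built
as a reusable library plus a small set of narrative analysis scripts. The
worked design it ships is an eczema (atopic dermatitis) exposure against
heart-failure outcomes, but every component is generic: any exposure and
any set of binary outcomes with per-variant (beta, SE, p, EAF, N) tables.

MR uses genetic variants as instrumental variables: because alleles are
randomized at conception, a variant that robustly raises an exposure and
has no other path to the outcome identifies the causal effect of the
exposure. For instrument *j* with exposure association γ̂ⱼ (SE σ_Xⱼ) and
outcome association Γ̂ⱼ (SE σ_Yⱼ), the package implements

* the Wald ratio θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ and its inverse-variance-weighted pooling
  θ̂ = Σwⱼθ̂ⱼ/Σwⱼ, wⱼ = γ̂ⱼ²/σ_Yⱼ² (fixed-effect and multiplicative
  random-effects SEs),
* the weighted median (consistent when ≥50% of the weight is valid), with a
  seeded parametric-bootstrap SE,
* MR-Egger regression Γ̂ⱼ = β₀ + β₁γ̂ⱼ (weights 1/σ_Yⱼ²), whose intercept
  β₀ measures average directional pleiotropy,
* Cochran's Q, the Egger intercept test, MR-PRESSO
  (global/outlier/distortion) and leave-one-out sensitivity,
* instrument selection (p < 5×10⁻⁸, greedy LD pruning at r² < 0.001 in a
  10,000 kb window, MAF > 1%, confounder exclusion list) with R² and
  F = R²(N−2)/(1−R²) strength reporting,
* allele harmonization with palindrome handling and proxy substitution,
* fixed-effect meta-analysis of study-level log odds ratios, Bonferroni
  classification, and analytic power for binary outcomes.

A synthetic summary-statistics generator with known ground truth
(`mrkit.simulate`) stands in for consortium GWAS downloads, so the entire
pipeline is testable offline. See `docs/methods.md` for the statistical
details and the generator's limitations.

## Worked example

The numbered scripts under `analysis/` run the full study shape on the
packaged synthetic datasets and write their tables under `results/`:

```bash
python analysis/01_build_datasets.py       # exposure + two HF-like outcomes
python analysis/02_select_instruments.py   # 21 -> 19 with audit trail
python analysis/03_causal_estimates.py     # IVW / weighted median / Egger
python analysis/04_pleiotropy_diagnostics.py
python analysis/05_meta_and_power.py       # pooling, threshold, power grid
```

`02_select_instruments.py` prints the selection accounting:

```
 significance: 21 -> 21
     ld_prune: 21 -> 20 (removed: rs12730935)
          maf: 20 -> 20
    exclusion: 20 -> 19 (removed: rs4713555)
selected 19 instruments
```

i.e. of 21 genome-wide-significant candidates, one member of the single
correlated pair is LD-pruned and one confounder-associated variant is
excluded, leaving 19 instruments; harmonization then reports exactly two of
them reached through proxy variants (r² > 0.8) absent from the smaller
outcome GWAS.

`05_meta_and_power.py` pools the two published per-study heart-failure
results, reconstructed from their printed confidence intervals:

```
published per-study results pooled (fixed effect):
  OR 1.07 [1.03, 1.10], p = 1.11e-04
  between-study Q = 0.78 (df 1), p = 0.38
  threshold 0.05/9 = 0.0056 -> significant
  per-study p = 0.004: significant
  per-study p = 0.01: suggestive
```

The pooled odds ratio 1.07 (1.03–1.10) clears the multiple-testing
threshold of 0.05/9 even though only one of the two contributing studies
does on its own — the point of pooling. The diagnostics script shows what a
clean instrument set looks like (Q p ≈ 1, Egger intercept p ≫ 0.05, no
MR-PRESSO outliers, leave-one-out stable without the dominant locus
rs61813875).

Everything is also reachable through a CLI (`mrkit run --config cfg.yaml`,
`mrkit validate`, `mrkit simulate`, `mrkit fixture`) for running the same
pipeline on your own summary-statistics files.

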