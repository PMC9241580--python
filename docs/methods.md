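# Methods

## Model and scope

`mrkit` implements two-sample Mendelian randomization (MR) at the
summary-statistics level. For each instrument *j* the exposure GWAS supplies
(γ̂ⱼ, σ_Xⱼ) and the outcome GWAS supplies (Γ̂ⱼ, σ_Yⱼ), aligned to a shared
effect allele. Under the instrumental-variable assumptions (association with
the exposure; independence from confounders; no path to the outcome except
through the exposure), the per-variant Wald ratio θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ estimates the
causal effect θ on the log-odds scale, and the estimators pool these ratios
in different ways that trade efficiency against robustness to pleiotropy.

The package covers the full chain: instrument selection and strength,
harmonization, estimation (IVW, weighted median, MR-Egger), diagnostics
(Cochran's Q, Egger intercept, MR-PRESSO, leave-one-out), fixed-effect
meta-analysis across outcome datasets, Bonferroni classification, and
analytic power. Genotype-level work (computing LD, liftover, VCF parsing)
and online variant-annotation services are out of scope; LD, exclusion and
proxy information arrive as small user-supplied TSV tables.

## Instrument selection

Stage order is fixed: significance filter (default p < 5×10⁻⁸), greedy LD
pruning, MAF filter (default MAF > 1%), confounder-exclusion list. Pruning
walks candidates by ascending p-value (ties broken lexicographically by
variant id, for determinism) and keeps a candidate only if its r² with every
already-kept variant inside a 10,000 kb window is below 0.001. Two
conservative/pragmatic choices where behaviour is genuinely open:

* an **unknown** r² between co-located variants prunes the later candidate —
  absence of LD evidence is not evidence of independence at close range;
* when positions are unavailable the window is unknowable; a pair is then
  treated as correlated only if the LD table says so, otherwise independent
  (with a warning). Blanket conservatism here would empty any selection run
  lacking positional data.

Strength: per-variant variance explained uses R²ⱼ = β²ⱼ/(β²ⱼ + N·σ²ⱼ)
(equivalently t²/(t²+N)), summed across instruments under the independence
the pruning stage enforces, and F = R²(N−2)/(1−R²), with F < 10 flagged as
weak-instrument territory.

## Harmonization

Allele pairs are matched directly, order-swapped, or via reverse complement;
a swap negates the outcome beta exactly once and reflects the outcome EAF.
Palindromic variants (A/T, C/G) cannot be strand-resolved from alleles, so
they are kept **only** when both EAFs sit on the same informative side of
the frequency limit (default 0.42): both below it, or both above 1−0.42.
Every other configuration — either frequency ambiguous, frequencies on
opposite informative sides, or a missing EAF — drops the variant. The
opposite-side case is often rescued by flipping in other toolchains; we drop
it as a deliberate safety choice (frequencies that disagree this strongly
may indicate a population-frequency mismatch rather than a strand flip), at
the price of instrument count. Instruments missing from the outcome are
substituted by a user-supplied proxy when its r² ≥ 0.8; the proxy's own
outcome association is used unchanged, without rescaling.

## Estimators

* **IVW**: θ̂ = Σwⱼθ̂ⱼ/Σwⱼ with first-order weights wⱼ = γ̂ⱼ²/σ_Yⱼ²
  (identical to a zero-intercept weighted regression of Γ̂ on γ̂ with weights
  1/σ_Yⱼ²). Fixed-effect SE is (Σwⱼ)^(−1/2); the primary multiplicative
  random-effects model inflates it by √(Q/(k−1)) floored at 1. Exposure-side
  uncertainty is ignored in the weights (the standard first-order choice;
  with F ≫ 10 the correction is negligible).
* **Weighted median**: the interpolated 50% point of the weighted empirical
  CDF of the ordered ratios (cumulative midpoints sⱼ = Σ_{i<j}wᵢ' + wⱼ'/2).
  The SE comes from a parametric bootstrap (default 1,000 replicates,
  mandatory seed) that redraws both γ̂* and Γ̂* and recomputes ratios and
  weights per replicate.
* **MR-Egger**: instruments are oriented so γ̂ⱼ > 0, then Γ̂ is regressed on
  γ̂ with a free intercept, weights 1/σ_Yⱼ². The intercept estimates the
  average directional pleiotropic effect; the slope is the causal estimate,
  consistent under InSIDE even when all instruments are pleiotropic. SEs are
  the unscaled WLS SEs multiplied by max(1, residual scale); inference uses
  t with k−2 df.

All effects stay on the log-odds scale internally; odds ratios appear only
in output tables. The 97.5% normal quantile is carried as 1.959964, with
rounding only at reporting.

## Diagnostics

**Cochran's Q** = Σwⱼ(θ̂ⱼ − θ̂_IVW-FE)², chi-square with k−1 df under
homogeneity; its p-value is reported alongside the Egger intercept test
(t-based, k−2 df).

**MR-PRESSO.** Observed residuals are scored against leave-one-out IVW
fits: RSS = Σⱼ(Γ̂ⱼ − θ̂₍₋ⱼ₎γ̂ⱼ)²/σ_Yⱼ². The simulated null redraws each
Γ̂ⱼ* around the **full** IVW fitted line θ̂γ̂ⱼ with SD σ_Yⱼ and recomputes
the leave-one-out estimates per simulated dataset. Centring the simulations
on the leave-one-out fits instead (as the reference implementation does)
lets noisy datasets inflate their own null — measured size ≈ 0.01 at
nominal 0.05 with k = 10 — whereas the fitted-line centring holds the
global test at its nominal level (≈ 0.047 in the same experiment); the
fitted line *is* the null model under test, so simulating from it is the
coherent parametric bootstrap. Empirical p-values use (1 + count)/(n_sim + 1)
and are never zero. The outlier test compares each variant's observed
contribution with its simulated distribution, Bonferroni-corrected over k
(α = 0.05); the distortion test, run only when outliers are flagged,
compares the outlier-removed shift with 1,000 random equal-size removals.
MR-PRESSO requires k ≥ 4 and n_sim ≥ 100.

**Leave-one-out** re-runs the primary IVW (mre) model dropping each
instrument in turn, or a single named instrument for targeted sensitivity
analyses (e.g. removing a dominant locus).

## Meta-analysis, multiple testing, power

Study-level results printed as OR (95% CI) are converted by
se = (ln hi − ln lo)/(2·1.959964) and pooled with fixed-effect inverse
variance weights; between-study Q is reported. Fixed effect is the chosen
model because at the two-study scale this package targets, between-study Q
stays below its df and DerSimonian–Laird collapses to fixed effect anyway.
The Bonferroni threshold is α/n_tests (0.05/9 ≈ 0.0056 in the packaged
worked example), with outcomes labelled significant / suggestive
(nominal-only) / null.

Power uses the non-centrality approximation behind the common web
calculators: ncp = N·R²_x·K(1−K)·ln(OR)², power = Φ(√ncp − z₁₋α/₂) +
Φ(−√ncp − z₁₋α/₂). It is an approximation (linearized logistic score test);
the test suite validates it against a 10,000-replicate simulation of the
genetic-score → binary-outcome design at n = 10,000, K = 0.5, R² = 0.05,
OR = 1.2, where it agrees within Monte-Carlo error.

## Synthetic data: what it does and does not emulate

The generator draws true instrument effects γⱼ log-uniformly in
[0.03, 0.3] (so a single variant can dominate, as one locus does in real
eczema instrument sets), EAFs uniform in [0.1, 0.9], and standard errors
from the standardized-trait approximation 1/√(2p(1−p)N). Defaults are the
dimensions of a large eczema-exposure / heart-failure-outcome design:
k = 19, n_exp = 116,863, n_out = 977,323, θ = 0.07. Pleiotropy scenarios:
`none`, `balanced` (zero-mean αⱼ), `directional` (αⱼ ~ N(μ_pl, σ_pl) for a
chosen fraction of instruments — the regime where IVW is biased but the
Egger intercept recovers μ_pl). One integer seed drives a single PRNG
stream; repeated calls are bit-identical.

What it does **not** emulate: LD between instruments, winner's-curse
selection of γ̂, sample overlap between exposure and outcome GWAS,
allele-frequency differences between cohorts, non-collapsibility of the
odds ratio, or case-control ascertainment. Passing recovery tests on this
generator therefore demonstrates correctness of the estimators under their
own model assumptions, not robustness to those real-data complications.

`make_reference_fixture()` is a separate deterministic construction: 21
genome-wide-significant candidates, one LD pair (r² = 0.5) whose
worse-ranked member is pruned, one variant on the exclusion list, and two
instruments absent from the outcome but rescued by proxies (r² = 0.92,
0.88), so selection returns 19 and harmonization reports exactly 2 proxy
substitutions. Five variant ids are real rsIDs used in published eczema
instrument sets; the other sixteen are synthetic placeholders
(rs1000001…), and all effect sizes are synthetic.

## Numerical choices and degenerate inputs

* p-values are clamped at 5e-324 so they stay in (0, 1]; empirical p-values
  cannot reach 0 by construction.
* A zero exposure beta makes the Wald ratio undefined and raises; k = 1
  falls back from IVW to the Wald ratio; weighted median and Egger require
  k ≥ 3, MR-PRESSO k ≥ 4, and the pipeline degrades gracefully (estimate
  without diagnostics) instead of failing.
* Zero-SE estimates (degenerate, e.g. a zero-width CI fed to `ci_to_se`)
  produce a warning and a point-mass estimate rather than an exception.
* Invalid summary rows are dropped-and-logged at parse time, not fatal;
  an empty final instrument set *is* fatal, with per-stage counts.

## Test problem sizes

Simulation-backed tests use: 200 replicates for estimator recovery at full
GWAS dimensions, 10,000 draws for the Q moment check, 500 null replicates
at n_sim = 300 for MR-PRESSO size, and 10,000 replicates for the power
oracle — sizes chosen so Monte-Carlo error is small relative to the effects
being checked while the whole suite stays fast on one core.

## Known limitations

First-order weights only (no second-order or exact weighting); no
mode-based estimators, MR-RAPS, multivariable MR or Steiger filtering; no
I²/Radial/Rucker framework; LD must be supplied, never computed; power for
binary exposures treats the exposure liability as standardized. The
palindromic rule and the missing-position pruning rule are deliberately
conservative conventions, documented above, not field-wide standards.
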