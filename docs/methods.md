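# Methods

This note records the models, parameter choices and numerical conventions
behind `metabomr`, and what the synthetic-data harness does and does not
establish about real-data behaviour.

## Study design

The package implements a two-stage causal screen of serum metabolites on
bone phenotypes.  Stage 1 builds a per-individual genetic risk score for
each metabolite from external GWAS weights and tests its
covariate-adjusted association with a continuous bone-density phenotype
(OLS) and binary fracture (logistic ML) in an individual-level cohort.
Stage 2 validates candidates with summary-level two-sample MR and a
sensitivity suite, fits a multivariable MR model to separate correlated
metabolites, and tests pathway over-representation of the implicated
metabolites.

Key thresholds (all overridable): instrument selection by greedy LD
clumping at p < 1e-5, r² ≤ 0.1, ±500 kb (PLINK window semantics), and at
the genome-wide 5e-8 when the bone trait is the exposure (reverse MR);
GRS significance at the Bonferroni level 0.05/486 ≈ 1.03e-4 over the 486
measured metabolites (the family size stays at the measured count even
though only the 309 chemically identified metabolites are analysed), with
p < 0.05 "suggestive"; pathway significance at 0.10 on raw hypergeometric
p-values, enrichment query = metabolites with p < 0.05.

## Synthetic data: what it emulates

Real inputs (a metabolome-wide GWAS of 7,824 individuals, bone-density
and fracture GWAS of ~430k, a ~400k-person cohort, 1000-Genomes-style LD
panels) are access-restricted or very large, so `synthetic_data`
generates structurally faithful stand-ins with known truth:

- **Effect sizes.** True exposure effects |γⱼ| ~ U(0.05, 0.3) with random
  sign.  The joint distribution of real metabolite effects is not
  published; the uniform range is a stand-in chosen to make instruments
  strong on average (mean F ≈ 90 at n = 7,824) while spanning the
  weak-to-strong range.  Outcome effects are Γⱼ = β·γⱼ + αⱼ with causal
  effect β (default 0.2 outcome SD per exposure SD).
- **Sampling noise.** Observed effects add independent noise at the
  GWAS standard error 1/√(2f(1−f)N) for allele frequency f ~ U(0.05,
  0.5); exposure and outcome samples never overlap (two-cohort design);
  p = 2Φ(−|β̂/se|) exactly.  Default sample sizes: 7,824 (exposure
  GWAS), 50,000 (outcome GWAS), 20,000 (cohort).
- **Pleiotropy.** `balanced` draws direct effects αⱼ ~ N(0, sd);
  `directional` draws N(mean, sd) and orients them with sign(γⱼ):
  directional pleiotropy is only defined relative to the
  exposure-increasing allele — with random orientation the planted mean
  would cancel by symmetry and no estimator could (or should) recover it.
  `plant_outliers` shifts chosen outcome betas by an exact amount for
  outlier-detection experiments.
- **LD.** Within a block, every SNP copies a shared latent haplotype
  allele with probability √r, giving pairwise allele (and genotype)
  correlation r in expectation; blocks share one allele frequency;
  genotypes are sums of two independent haplotypes, hence Hardy-Weinberg.
  This gives tunable, seedable LD; it does not reproduce human LD decay,
  haplotype structure or imputation noise.
- **Cohort.** Covariates: age ~ N(57, 8²), sex ~ Bernoulli(0.5), height
  and weight with a sex offset, and ten exactly orthogonal PC columns
  (QR of a Gaussian matrix, unit variance).  The latent metabolite is
  X·γ + N(0, 1); the continuous phenotype adds β·metabolite, small fixed
  covariate effects and N(0, 1) noise; fracture is Bernoulli-logistic
  with prevalence 12.5% (53,184 cases of 426,795 in the source fracture
  GWAS) and decreasing in the bone phenotype.  No population
  stratification or relatedness is modelled — passing tests show
  estimator correctness under the stated model, not robustness to those
  real-data complications.

## Estimators and conventions

- **Wald ratio / IVW.** θⱼ = Γⱼ/γⱼ with first-order SE σ_Yⱼ/|γⱼ|
  (exposure-side noise ignored, the convention of the standard MR
  packages).  IVW weights γⱼ²/σ_Yⱼ² (≡ no-intercept WLS).  Cochran's Q
  with df = J−1; `auto` switches to multiplicative random effects — SE
  inflated by max(1, √(Q/df)) — when the Q p-value falls below 0.05 (the
  switch level is a flag; the source design states the switch without a
  level).  All p-values are two-sided normal, not t.
- **MR-Egger.** SNPs oriented so γⱼ ≥ 0, then WLS of Γ on γ with
  intercept, weights 1/σ_Yⱼ²; coefficient covariance inflated by
  max(1, Q/(J−2)).  The intercept estimates average directional
  pleiotropy.
- **Weighted median.** Cumulative-midpoint interpolation of the ordered
  ratios at probability 0.5; SE by parametric bootstrap (redraw γ, Γ
  from their sampling distributions; default 1000 draws, seeded).
- **Mode.** Maximum of a 1/se²-weighted normal-kernel density over the
  ratios on a 512-point grid spanning [min θ − 3h, max θ + 3h]; bandwidth
  h = φ·0.9·min(sd, MAD_normalized)·J^(−1/5), φ = 1; grid argmax ties
  break to the smallest value; bootstrap SE as above.
- **MR-PRESSO.** Observed RSS = Σⱼ (Γⱼ − β̂₋ⱼγⱼ)²/σ_Yⱼ² with
  leave-one-out IVW predictions.  The null redraws *both* γ*ⱼ ~ N(γⱼ,
  σ_Xⱼ) and Γ*ⱼ ~ N(β̂₋ⱼγⱼ, σ_Yⱼ) and recomputes the statistic; the
  observed residual carries exposure-side noise, so omitting the γ
  redraw makes the global test reject ~17% at nominal 5% instead of ~5%.
  Empirical p-values use (1 + #{≥ observed})/(n_sim + 1), so n_sim =
  1000 floors the per-SNP p at ~1/1001; outlier calls are
  Bonferroni-controlled across the J instruments at 0.05.  The
  distortion test compares the raw-minus-corrected estimate change with
  removal of 1000 random same-size subsets; it is skipped (flagged) when
  no outliers are called.
- **MVMR.** β̂ = (ΛᵀWΛ)⁻¹ΛᵀWλ̂_BMD, W = diag(1/σ_Yⱼ²), no intercept
  (the structural equation has none); covariance inflated by
  max(1, Q/(J−K)); σ² reported as Q/(J−K).  The instrument set is the
  intersection of SNPs observed in every exposure table and the outcome
  table (the summary tables in scope are dense; proxy lookup is out of
  scope).
- **Enrichment.** Upper-tail hypergeometric including the observed
  overlap; universe = the library universe unless a background is
  supplied; raw p-values against α = 0.10 with an informational
  Benjamini-Hochberg column (the source design reports raw pathway
  p-values).

## Known finite-sample behaviour

Because exposure effects enter with sampling noise and the Wald SE is
first-order, two small, theoretically predicted deviations appear under
the default simulation conditions and are asserted as such in the tests:

- the mean fixed-effect IVW estimate is attenuated to β·λ with
  λ = E[γ²]/(E[γ²] + E[σ_X²]) ≈ 0.989 at n_exposure = 7,824 (measured
  0.198 for β = 0.2 over 200 replicates);
- the mean Egger intercept under planted directional pleiotropy 0.05
  carries the analogous regression-dilution shift ≈ β·(1−λ_w)·E_w|γ| ≈
  +0.002 (measured 0.052);
- 95% CI coverage of fixed IVW is slightly sub-nominal (91.9% ± 0.9 over
  1000 replicates) because the analytic SE omits the exposure-noise
  term.  A second-order SE would restore coverage but departs from the
  standard convention implemented here.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed (numpy `default_rng`);
the pipeline manifest records config, seed, per-stage row counts and a
SHA-256 over all written artifacts, and a rerun with the same config and
seed is byte-identical.  Simulation-based checks use 100–200 replicates
with 10–50 instruments and cohorts of 2,000–5,000 — sizes chosen so the
full suite runs on a laptop core in a few minutes while keeping
Monte-Carlo error well below the tolerances asserted.  The demo pipeline
uses 4 metabolites × 40 SNPs, a 1,000-sample LD panel and a 5,000-person
cohort.

## Limitations

- The QC list, thresholds and estimator conventions mirror one published
  study design; other designs (Steiger filtering, MR-RAPS, conditional
  instrument selection, additive-τ² random effects) are out of scope.
- The GRS fracture model defaults to logistic regression; the source
  design is silent on the binary-outcome model, and a linear-probability
  family is exposed for comparison.
- Pathway p-values depend on the library and background; with the
  bundled synthetic libraries they validate the test's math, not any
  biological enrichment claim.
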