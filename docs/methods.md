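# Methods

## The analysis chain

The package operationalizes one causal question — how much of an
exposure's effect on a continuous disease-severity outcome flows through
DNA methylation — as a fixed sequence of stages, each consuming only the
typed containers in `methmediate.datatypes`:

1. **Cohort outcome models** establish the exposure–outcome association:
   OLS of severity on exposure frequency plus confounders, a Cox
   proportional-hazards model of mortality (Efron tie handling, Wald
   intervals on the hazard ratio), and a log-rank test for trend across
   ordered frequency groups with equally spaced scores and the standard
   multivariate-hypergeometric variance.
2. **Dual EWA scans** select candidate mediators.  Methylation (the beta
   value, a fraction in [0, 1]) is the dependent variable; each CpG is
   regressed on the phenotype plus covariates.  The exposure scan
   contrasts the persistent-use and no-use groups only (inconsistent
   longitudinal reporters are excluded); the severity scan uses the full
   sample and additionally adjusts for the top-2 principal components of
   the 1000 most CD4-relevant CpGs, since the severity score contains a
   CD4 component and would otherwise over-select CD4-tracking CpGs.
   Candidates must pass p < 0.001 in both scans (strict inequality; ties
   at the printed threshold are excluded).  Biologically forced additions
   are labelled as such.  Each scan reports the genomic inflation factor
   λ = median(χ²₁(1−p)) / 0.4549364.
3. **Mediation** fits, per candidate M, the mediator model
   M = β₀X + ΣβᵢCᵢ + ε₂ and the outcome model
   Y = α₀X + α₁M + Σαᵢ₊₁Cᵢ + ε₁ by OLS on the two-group subset, with
   ACME = α₁β₀, ADE = α₀, TE = α₀ + α₁β₀ and PM = ACME/TE.  The joint
   model keeps per-mediator mediator models but one outcome model with
   all mediators, so joint ACME = Σαⱼβ₀ⱼ.  TE = ADE + ACME and
   PM·TE = ACME hold exactly by construction (tested to 1e-10).
4. **Sensitivity analysis** re-expresses ACME as a function of the
   correlation ρ between ε₁* (the error of the outcome-on-exposure model
   with the mediator *excluded*) and ε₂, following the
   Imai–Keele–Yamamoto linear-SEM result:
   ACME(ρ) = β₀(σ₁/σ₂)(ρ̃ − ρ√((1−ρ̃²)/(1−ρ²))).  ACME(0) equals the
   point-estimate ACME exactly (a Frisch–Waugh identity), the curve is
   strictly monotone in ρ, and its unique zero is the fitted residual
   correlation ρ̃ — reported as an analytic root and rounded to the 0.05
   grid over (−0.95, 0.95).  The sign of ρ̃ follows the sign of α₁, which
   is why mediators that are hypomethylated by the exposure (β₀ < 0,
   ACME > 0 ⇒ α₁ < 0) report negative crossings.
5. **Two-step MR** validates direction: step 1 combines external GWAS
   instrument effects on the exposure (harmonized to the cohort's ALT
   alleles, p < 1e-5, greedily LD-pruned at r² < 0.1 on in-sample
   dosages) with in-sample SNP→CpG regressions; step 2 instruments each
   CpG with its cis-meQTLs (same chromosome, closed 1 Mb window, 1-based
   coordinates, p < 0.01, pruned) against SNP→severity regressions.
   Both use the fixed-effect IVW estimator with first-order weights; a
   single instrument reduces exactly to the Wald ratio.  SNP-level
   regressions are computed by residualizing trait and dosages on the
   shared covariates once (Frisch–Waugh–Lovell), which reproduces the
   per-SNP full fits exactly.  The cell-proportion MR repeats step 1
   with each of the six cell fractions as outcome as a negative control.

## Inference choices

- **Bootstrap:** nonparametric over whole samples; B = 10,000 by default
  (configurable; tests use 1000–2000).  Percentile intervals; the
  two-sided p-value is 2·min(P(draw ≤ 0), P(draw ≥ 0)) floored at 1/B.
  Each bootstrap iteration recomputes both models from one Gram matrix of
  the stacked [C | X | M | Y] columns, so a fixed seed gives bit-identical
  output and the loop stays fast at desk scale.
- **Proportion mediated** is reported unclipped (it may exceed 1 or be
  negative); it is flagged undefined when |TE| ≤ 1e-12 rather than
  reported as a number.
- **Multiplicity:** the Bonferroni threshold α/m over the candidate set.
- **Degenerate inputs:** constant CpGs are flagged (effect 0, p = 1), not
  fatal; monomorphic SNPs likewise.  Rank-deficient designs, zero events
  in the Cox model, all-zero instrument effects in IVW, and grids with
  |ρ| ≥ 1 are fatal with named offenders.
- **Missing methylation** is imputed to the per-CpG mean at read time
  (count logged); a defined policy keeps the scans total.
- **Coordinates** are 1-based inclusive throughout; the cis window is a
  closed interval.
- **LD pruning** sorts SNPs by ascending p (ties broken by identifier) and
  keeps a SNP iff its squared dosage correlation with every kept SNP is
  below the cut; SNPs with zero variance never block others.

## The synthetic-cohort generator

`SimParams` defaults define the study conditions the test-suite operates
under; they are chosen once and are not tuned per test.

- **Cohort structure:** n = 900 samples; ordinal exposure frequency 0–5
  with baseline probabilities (38.7, 37.6, 8.5, 7.2, 2.7, 5.3)% and
  longitudinal groups (persistent 30.3%, none 23.1%, inconsistent the
  rest), both cut from one latent liability so the two exposure codings
  share a single construct.  The liability carries the weak genetic
  instrument effects (8 SNPs × 0.15 SD/allele ≈ 7% of variance —
  deliberately marginal instruments).  Covariate marginals: age
  N(50, 8²); 2.5% female; race 20/67/13% (Caucasian / African-American /
  other, with the first ancestry PC separating the groups); 53% smoking;
  78% adherence.
- **Methylation:** logit(M) = baseline + β₀·dose + meQTL + cell-mixture +
  batch + module factor + N(0, 0.45), mapped through the logistic
  function, so all betas are strictly inside (0, 1).  Exposure dose is
  1 / 0.5 / 0 for persistent / inconsistent / none, making the
  persistent-vs-none contrast equal the generating effect.  Cell
  proportions are Dirichlet(60·base) around a blood-like base; ~30% of
  CpGs carry a strong CD4 loading (sd 30 on the logit), which makes the
  top-2 PCs of the CD4-relevant submatrix explain > 80% of its variance
  — the property the CD4-PC covariate construction expects.  Mediator
  CpGs share a module factor (loading 0.4) emulating co-regulation of
  an antiviral gene module.
- **Effect calibration** (a stated calibration, not a measured value):
  α₀ = 0.28, α₁ⱼ = −0.33 per beta unit, β₀ⱼ = −0.30 on the logit scale
  (≈ −0.06 beta units), 12 mediators.  These sizes were fixed by power
  arithmetic so that (i) the true joint proportion mediated is ≈ 0.47,
  (ii) single-site proportions mediated land in the 11–30% band —
  single-site fits double-count the shared module, exactly the mechanism
  by which summed single-site proportions can exceed 100% — and (iii)
  planted signals are detectable by each pipeline stage at its working
  sample size.  The severity outcome is on a compressed unit-noise scale
  (intercept 39, σ_y = 1): the generator reproduces effect *ratios*, not
  the raw variance of a clinical severity index.
- **Truth on the analysis scale:** because effects are injected on the
  logit but analyzed on raw betas, `SimTruth` reports the induced
  beta-scale exposure effect β₀ⱼ* as the average per-sample
  counterfactual difference (dose 1 vs 0, all other generated terms held
  fixed), so true ACMEs are directly comparable to regression estimates.
- **Survival:** exponential with rate 0.03·exp(log(1.10)·frequency),
  exponential censoring (rate 0.08) capped administratively at 10 years.
- **Genetics:** independent SNPs, dosages Binomial(2, maf),
  maf ~ U(0.05, 0.5); 3 cis-meQTLs per mediator at ±500 kb with logit
  effect 0.5/allele; the external GWAS table reports instrument betas
  with SE 0.025 (some rows on the other allele, exercising
  harmonization) plus null filler rows that the p-filter must reject.
- **Confounder injection:** `inject_unmeasured_confounder` adds a latent
  U ~ N(0,1) to one mediator (×γ_m) and the outcome (×γ_y) and returns
  the induced error correlation
  ρ* = γ_mγ_y / √((σ_m²+γ_m²)(σ_y²+γ_y²)), with the pre-injection
  residual SDs estimated by OLS unless supplied.  Choosing γ = σ̂ gives
  ρ* = 0.5 exactly, the case the sensitivity analysis is tested against.
- **One RNG stream** per cohort, seeded from `SimParams.seed` via
  `SeedSequence.spawn`, one child per component; the same seed is
  bit-reproducible.

**What the generator does not emulate** — array chemistry and probe bias,
batch chips beyond a low-rank negative-control structure, realistic LD
(SNPs are independent, so in-sample pruning is exercised by planted
duplicates in tests rather than haplotype structure), bimodal beta
distributions, non-linear or interacting mediator effects, and informative
censoring.  Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under the assumed linear-additive data-generating
process; they do not certify behaviour under array artifacts or model
misspecification in real cohorts.

## Problem sizes used by the test suite

Chosen as the package's own benchmark sizes: bootstrap coverage over 100
cohorts (n = 2000, B = 2000) with a single planted mediator sized to a
proportion mediated of ≈ 0.3; type-I error over 500 null-path cohorts
(n = 400, B = 1000, sex dropped from the covariate list so every
replicate's design is full rank at that n); ρ-recovery at n = 5000;
trend-test calibration over 1000 replicates at n = 200; the null-scan
inflation check at 50,000 CpGs (n = 250); MR end-to-end recovery at
n = 5000 with 6 cis-meQTLs per mediator.  The cell-proportion
negative-control MR is asserted per cell type (each non-significant in
≥ 80% of replicates; the observed rate is ≈ 95%) — the joint event "all
six simultaneously non-significant" has null probability ≈ 0.95⁶ ≈ 0.74
and is therefore not a usable acceptance bound.

## Known limitations

- The mediation models are strictly linear and additive: no
  exposure–mediator interaction, no binary outcomes, no penalized
  high-dimensional mediator selection.
- Step-1 MR interprets estimates per external-GWAS liability unit; no
  rescaling to the cohort's frequency coding is attempted.
- The joint-mediation bootstrap conditions on the fixed mediator set; it
  does not re-run selection inside resamples, so selection uncertainty is
  not propagated.
- LD pruning uses the cohort's own dosages as the reference panel.
- The Cox stage reports no proportional-hazards diagnostic beyond the
  model fit itself; time-varying effects are out of scope.
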