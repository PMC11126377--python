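# Methods

## Model and procedure

`rareburden` tests whether rare, putatively functional variants in a gene
are collectively associated with a binary phenotype in a case-control
cohort. The procedure per gene:

1. **Qualification and QC.** A biallelic variant qualifies if its minor
   allele frequency is ≤ 0.01 in cases, in controls, or both (rare in either
   group suffices). Variants are excluded when more than 10% of pooled
   genotypes are missing, or when the pooled heterozygote count is smaller
   than both pooled homozygote counts (a crude Hardy–Weinberg-style guard
   against genotyping artefacts). Records whose alternate allele has pooled
   frequency > 0.5 are flipped to the minor allele before rarity testing.
2. **Weights.** Each kept variant receives
   `w = w_MAF · w_annotation` with
   `w_MAF(maf) = w_cap + (w_0 − w_cap)(1 − maf/maf_cap)²` — the parabola
   through (0, 10) and (0.01, 1) with vertex at the cap, so the weight
   approaches 1 smoothly at the rarity cutoff — and an annotation weight of
   100 (LOF), 5 (nonsynonymous; +5/+10 for PolyPhen possibly/probably
   damaging, +20 for SIFT deleterious, additive and co-occurring), 20
   (splice region), 10 (inframe indel) and 1 for synonymous/UTR/intronic
   classes. The MAF entering the weight is the overall (pooled) MAF,
   clamped at the cap for variants kept through the one-group rarity rule.
3. **Score.** Per subject, the gene-wise burden score is the weighted sum
   of alternate-allele dosages. Missing genotypes are imputed to the
   per-variant mean dosage over genotyped subjects (pooled), before
   weighting; by linearity this equals assigning the subject-wise average
   score contribution.
4. **Test.** Logistic regression of case status on sex + 20 principal
   components, with and without the score; the LRT statistic is referred to
   χ²₁. Reporting uses the signed log p-value, SLP = ±(−log₁₀ p), signed by
   the fitted score coefficient (positive = higher burden in cases). The
   Bonferroni threshold on this scale is −log₁₀(α/n_tests).
5. **Category decomposition.** Kept variants are partitioned into disjoint
   reporting categories by a most-severe-wins ladder:
   LOF > inframe indel > PolyPhen probably > PolyPhen possibly >
   SIFT deleterious > protein altering > splice region > 5'UTR > 3'UTR >
   synonymous > intronic. Per-subject category allele counts (fractional
   after imputation) enter a single joint logistic regression with the same
   covariates; each category's OR = exp(β) with Wald 95% CI
   exp(β ± 1.96·SE) and SLP from the Wald χ²₁ p-value, signed by OR vs 1.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `maf_cap` | 0.01 | rarity cutoff and MAF-weight vertex |
| `w_at_zero`, `w_at_cap` | 10, 1 | MAF-weight endpoints |
| base weights | LOF 100, nonsyn 5, splice 20, indel 10, others 1 | annotation severity |
| PolyPhen / SIFT increments | +5/+10, +20 | extra weight for flagged nonsynonymous variants |
| missingness limit | 10% pooled | QC exclusion |
| covariates | sex + 20 PCs | confounding control |
| CI multiplier | 1.96 | normal-approximation Wald interval |

The LOF/nonsynonymous/PolyPhen/SIFT weights are the published convention
this package follows; the weights for categories outside that list
(synonymous, UTRs, intronic = 1; splice region = 20; inframe indel = 10)
are this package's defaults and can be overridden through the plain-text
weight config (`rareburden/data/default_weights.cfg` documents the format).

## Numerical choices

- Logistic likelihoods are maximised by Newton iterations (statsmodels
  `Logit`, tol 1e-8 on the score, 100-iteration cap). Separation and
  non-convergence raise a `ConvergenceError` naming the fit rather than
  returning huge coefficients; transient overflow inside the iterations is
  tolerated. The covariates-only model is fitted once per cohort and reused
  across genes.
- A zero-variance burden score returns the defined degenerate result
  p = 1, SLP = 0, direction "null", so tabulation never fails.
- Zero-variance categories are dropped from the joint design and reported
  with blank OR cells; the LRT χ² is floored at 0 against tiny negative
  round-off.
- When both PolyPhen and SIFT flag a variant, the weight increments add;
  in the disjoint category ladder PolyPhen classes outrank SIFT. The
  ladder position of doubly-flagged variants is a documented choice — the
  partition itself, not the weights, is affected.

## The simulator — what it does and does not emulate

`simulate_cohort` draws, from one seeded generator: per-variant MAFs
log-uniform on [10⁻⁴, 10⁻²] (a heavy-tailed rare spectrum truncated at the
cutoff); a reporting category per variant with probabilities proportional
to the per-gene variant counts typical of a large exome cohort (intronic ≫
nonsynonymous ≫ LOF ≫ indels); Hardy–Weinberg genotypes
(dosage ~ Binomial(2, maf)); genotypes masked missing completely at random
(default 1%); sex ~ Bernoulli(0.5) and 20 i.i.d. standard-normal PCs; and a
prospective phenotype with
logit P(case) = baseline + Σ_c logOR_c·count_c + β_sex·sex + Σ β_k·pc_k,
the baseline targeting ~22.6% prevalence (the hyperlipidaemia rate in the
cohort this emulates, 106,091 cases of 469,765 participants). Phenotypes
are generated from the *true* pre-masking counts; tallies exposed to the
analyst are computed after masking.

Deliberately not emulated: linkage disequilibrium between variants,
population-stratification confounding (the PCs are pure noise, so passing
tests say nothing about stratification robustness), relatedness,
genotyping-error structure, and per-gene heterogeneity of effect within a
category. Calibration and recovery results on these simulations therefore
validate the statistical machinery, not robustness to those real-data
complications.

Default problem sizes used in the checked experiments — 2,000 null genes at
n = 5,000 for SLP calibration, 100 replicates at n = 50,000 with ~0.5%
cumulative LOF carrier frequency for odds-ratio recovery — were chosen as
the smallest scales at which the asymptotic χ² and Wald approximations are
expected to hold comfortably for rare-variant counts.

## Design choices where the design was open

- **Parabola form.** Two points do not pin down a parabola; the vertex is
  fixed at (maf_cap, w_cap), the only supported form, so the weight is
  strictly decreasing and flattens at the cutoff.
- **Pooled vs per-group QC.** The missingness and heterozygote-deficit
  rules are evaluated on pooled cases+controls tallies. For the het-deficit
  rule this is the conservative reading (fewer exclusions than requiring
  the deficit in each group separately).
- **Overall MAF for weighting.** Weights use the pooled MAF of the minor
  allele; variants kept because they are rare in only one group are clamped
  to the cap (weight 1) rather than extrapolating the parabola beyond it.
- **Disjoint category partition.** The most-severe-wins ladder above is a
  documented convention; any partition consistent with LOF/indel dominance
  would change only how doubly-flagged nonsynonymous variants are labelled.
- **Prospective phenotype simulation.** Disease status is assigned by the
  logistic model over the whole simulated population rather than by
  case-control sampling, keeping simulated ORs directly interpretable.

## Known limitations

- Asymptotic χ² and Wald inference only; no exact, permutation or
  saddlepoint small-sample corrections, so very sparse genes (a handful of
  carriers) can be mildly miscalibrated.
- One phenotype, unrelated-subject logistic model; no mixed models or
  kinship adjustment.
- The annotation table is consumed pre-digested; the package does not run
  VEP/PolyPhen/SIFT or derive phenotypes from health records.
- Multiallelic VCF sites are decomposed into biallelic records; records
  whose genotypes cannot be decomposed are treated as missing calls.
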