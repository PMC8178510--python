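# Methods

This note records the statistical models implemented in `mirqtl`, the
assumptions behind them, the defaults and why they were chosen, what
the synthetic-cohort generator does and does not emulate, and the
numerical choices a maintainer would want to know about.

## The screen

The package operationalises a common regulatory-genomics argument: a
non-coding GWAS risk locus may act by perturbing the expression of a
nearby miRNA (a *cis*-eQTL), and that miRNA may in turn repress mRNA
targets in *trans*, with phenotypic consequences. The screen has three
statistical layers — a cis association scan, an instrumental-variable
step, and a battery of phenotype filters — preceded by genotype and
expression QC.

### Genotype QC

Imputed variants are filtered on four criteria: imputation info score
> 0.7, minor allele frequency > 5%, per-call maximum genotype
probability > 0.7, and Hardy–Weinberg equilibrium p > 10⁻⁶. Two
interpretations were genuinely open:

* The posterior-probability criterion is applied **per call**, not per
  variant: a low-confidence call becomes missing rather than removing
  the variant. This matches standard imputation-QC practice and keeps
  the criterion distinct from the info-score filter.
* HWE uses the 1-df chi-square goodness-of-fit test on best-guess
  genotypes (dosages rounded to the nearest integer, ties to even).
  At a 10⁻⁶ threshold the chi-square and exact tests agree for any
  realistic sample size; the chi-square version is exactly
  reproducible from genotype counts. Monomorphic variants return
  p = 1 (no measurable departure).

MAF is computed as mean dosage / 2 over non-missing calls. LD is the
squared Pearson correlation of unphased dosages (composite r²) —
phase is not available after imputation filtering, and composite r²
is the quantity the tag-expansion threshold (r² > 0.5, strict) is
applied to. Tag expansion searches a 1 Mb window either side of the
tag; the output is sorted positionally and is invariant to tag order,
with each captured variant annotated by its strongest tag (ties broken
by distance, then tag id).

Ancestry assignment fits a two-component PCA on standardized dosages
of the variants shared with a labelled reference panel (cohort and
reference merged, mean-imputed at missing calls) and labels each
cohort sample by the majority vote of its 5 nearest reference samples
in PC1–PC2, ties broken by smallest mean distance. The choice of
k = 5 is a convention; with the population separations the method is
meant for (continental-level, Fst ≈ 0.1) the assignment is insensitive
to k.

### Expression preparation

Small-RNA expression enters as RPM and is transformed to log₂(RPM+1).
Outliers are masked per feature in a **single pass**: entries further
than 3 SD from the feature mean (both computed once, on all values)
become missing. Iterating the rule would remove progressively more
data and make the mask order-dependent. "Absent" is defined as RPM
exactly 0 — the only unambiguous reading for count-derived RPM — and
features absent in more than 20 samples are dropped (more than 10 per
group at the differential-expression stage, where the same operation
is reused).

Copy number enters the cis model as a single ordinal: gain (+1) /
neutral (0) / loss (−1), thresholded at ±0.3 on the segment log₂
copy-ratio; pre-categorized input is accepted verbatim. Promoter
methylation is the mean beta over TSS200/TSS1500 probes (pooled — the
two regions describe the same promoter), cut at fixed quartiles
(0.25, 0.5, 0.75) into levels 0–3; a mean exactly at a cutpoint falls
in the lower category. Fixed cutpoints were preferred over data-driven
quantiles so the covariate coding does not change with cohort
composition.

### cis-eQTL scan

For every SNP–feature pair whose transcription-start anchor (feature
start on the + strand, end on the −) lies within the window (default
1 Mb), the model

    miRNA_i = b0 + b1 G_i + b2 Age_i + b3 Sex_i + b4 CNV_i + b5 CpG_i + e_i

is fitted by ordinary least squares on pairwise-complete samples; age
is numeric, sex binary, and CNV and CpG enter as single numeric
ordinals (one coefficient each). The pair — not the SNP — is the test
unit. The implementation fits each pair directly (no residualization
shortcut), so equality with a reference per-pair OLS is structural;
the test suite verifies it against statsmodels to 10⁻⁸ relative error
including under injected missingness. Benjamini–Hochberg q-values are
computed **jointly across all tested pairs** in the run (the
multiplicity universe is configurable but global by default), and
associations are called at FDR 0.1. Pairs with a constant genotype or
a rank-deficient design are skipped with a recorded reason. Output
order is deterministic: ascending p, then |t| descending, then SNP and
feature ids.

### Mendelian randomization

With a single instrument the 2SLS estimator reduces exactly to the
Wald ratio cov(G, Y)/cov(G, X); the package computes it in that form,
with the standard IV variance  se² = s²ᵤ·S_GG/S_GX²  (residuals taken
at the IV slope). The weak-instrument statistic is the first-stage
F = (n−2)R²/(1−R²) of the exposure-on-dosage regression, with its
upper-tail p on (1, n−2) df; "significant instrument" is rejection of
the zero-first-stage null at BH FDR < 0.05 across the axes tested at
that stage. No F > 10 rule of thumb is imposed. A first-stage
covariance that is numerically zero (relative tolerance 10⁻¹⁰) raises
a distinct error instead of returning an arbitrarily large ratio; a
merely weak instrument passes through with its statistics, to be
screened by the FDR step.

One IV test is performed per (eSNP, mRNA) axis through the eSNP's
associated miRNA; a gene passes the MR stage if **any** of its axes
survives the weak-instrument screen. The aggregation rule across axes
was an open choice; "any axis" is the most permissive coherent rule
and the funnel's later stages provide the specificity.

### Candidate funnel

Criteria are applied in a fixed order — integrated target-prediction
score ≥ 0.1; at least 100 present calls (non-missing, RPM > 0);
weak-instrument FDR < 0.05; differential expression (FDR < 0.01 and
|log₂FC| > 0.5); survival predictivity (Cox FDR < 0.05) — with BH
applied **within** the MR, DE and survival stages separately, over the
genes reaching each stage. A gene missing the statistic required at a
stage fails that stage with reason "missing"; it never silently
passes. Survivor counts are non-increasing by construction and the
result is invariant to input gene order.

### Differential expression and survival

The tumor-vs-normal test is Welch's unequal-variance t on log₂ values
(a paired variant is available; unpaired is the primary since normals
are typically a subset of patients rather than a complete matching),
with log₂FC = mean(tumor) − mean(normal) and BH FDR. The DE call
requires both the FDR and the fold-change threshold.

The survival screen dichotomizes each feature at the cohort median
(high = strictly above) and fits a Cox proportional-hazards model with
a single covariate. The fitter is Newton–Raphson on the partial
likelihood with **Efron** handling of tied event times, step-halving
to guarantee ascent, convergence at |Δβ| < 10⁻⁹, and a cap |β| ≤ 20
with a separation flag when the likelihood is monotone. It matches
lifelines' `CoxPHFitter` to 10⁻⁶ on tied data (verified in tests;
lifelines is used only as the independent cross-check, plus for the
Kaplan–Meier curves and log-rank test, which are standard steps).
Hazard ratios are reported with Wald 95% intervals.

### 2×2 association

The odds ratio of a 2×2 exposure-by-outcome table is the cross-product
(a·d)/(b·c), identical to the exponentiated slope of a logistic
regression of the outcome on the binary exposure (verified against a
GLM fit in tests); the p-value is the Wald test with
se(log OR) = √(1/a+1/b+1/c+1/d). With a zero cell no correction is
applied by default — the OR is reported as 0/∞ with a flag, Haldane's
+0.5 available as an option. In the bundled clinical table the
exposure is always the high-expression column, while the outcome
level used as numerator is stored per characteristic, because the
published codings differ between characteristics (e.g. Sex is
male-coded while the others use their first listed level).

## The synthetic cohort generator

The generator is a forward model of everything the analysis assumes,
not a simulation of any real dataset:

* **Haplotypes** follow a two-state Markov chain along one chromosome:
  each allele copies its left neighbour with probability `ld_decay`,
  otherwise draws from the variant's allele frequency (uniform in
  `maf_range`, default 0.1–0.4). This gives tunable pairwise r² that
  decays geometrically with distance; diploid dosages are sums of two
  independent haplotypes, so each variant is marginally in HWE.
* **miRNA expression** is the cis-eQTL linear predictor plus Gaussian
  noise (sd 1 by default), with a baseline of 6 log₂ units and age
  entering centred at 65 so the baseline stays interpretable; values
  are floored at 0, the absence level of the log₂(RPM+1) scale.
  Covariates: age ~ Normal(65, 8) truncated to [30, 90]; sex
  Bernoulli(0.5); CNV ∈ {−1,0,+1} with probabilities (0.2, 0.6, 0.2);
  CpG level uniform on {0..3} — drawn per (sample, feature) for CNV
  and CpG since both are feature-specific.
* **mRNA expression** is the trans predictor (slope times the
  realized miRNA level) plus noise, baseline 8; an optional shared
  confounder (`confounder_sd`) can hit both layers to create the
  situation IV estimation is for.
* **Tumor shifts** add a per-feature log₂ offset to tumor samples
  (tumor fraction 0.8 by default, a typical tumor/normal imbalance).
  Note that a shift planted on a miRNA propagates into its trans
  targets scaled by the trans slope; cascade fixtures account for
  this.
* **Survival** is exponential with per-sample log hazard equal to the
  configured log HRs times standardized expression, baseline median
  24 months. Censoring is independent Uniform(0, c) with c solved
  numerically (Brent) so the expected censoring fraction matches the
  target (default 30%, enough events to keep screens well powered at
  the cohort sizes used).
* **Determinism**: all randomness flows from one root seed through
  named `SeedSequence` child streams (allele frequencies, haplotypes,
  QC fields, covariates, group labels, the two noise layers,
  confounder, survival, censoring, candidate scores), so identical
  configurations are bit-identical and each stage is independently
  reproducible.

What the generator does **not** emulate: realistic recombination maps
or demography, imputation uncertainty structure, count-level
sequencing noise, batch effects, or correlated co-expression modules.
Passing tests therefore demonstrate the estimators' statistical
behaviour under their stated assumptions — linear effects, Gaussian
noise, proportional hazards, independent censoring — not robustness
to the violations real data adds.

## Simulation studies and problem sizes

The study sizes used by the test suite and `scripts/acceptance.py`:

* **Scan vs direct OLS**: 3 seeded cohorts, 50 variants × 10 miRNAs
  (500 pairs), n = 120, 5% missingness; worst relative error on
  (β₁, t) vs statsmodels, required < 10⁻⁸ (observed ~10⁻¹²).
* **Null calibration**: 200 replicates of a 10 × 10 pair universe at
  n = 100 with all effects zero; mean false-discovery proportion at
  q ≤ 0.1 must be ≤ 0.12 (under the global null the FDP is the
  indicator of any call, so its mean estimates the family-wise error
  ≈ 0.1 with Monte-Carlo sd ≈ 0.02).
* **Planted-effect recovery**: β₁ = 0.8 at allele frequency 0.3,
  σ = 1, n = 227, 100 replicates in a 100-pair universe; detection at
  q ≤ 0.1 in ≥ 90% and mean β̂₁ within 5% of truth.
* **IV under confounding**: x = 0.5g + u + e, y = 0.5x + u + e with
  u ~ N(0,1) shared and e ~ N(0, 0.5); n = 5000, 100 replicates. The
  naive slope is biased by cov(x,u)/var(x) ≈ 0.74 while the Wald
  ratio's median absolute error stays ≈ 0.03; Wald and explicit 2SLS
  agree to 10⁻¹⁰ (they are the same estimator).
* **Cox recovery**: two-group exponential with true HR 0.46, n = 1000,
  uniform censoring at scale 4.5 (≈ 30% censored under the protective
  group effect), 100 replicates; mean ĤR within 10% of truth.
* **Planted cascade**: n = 400, one cis effect (1.2), one trans effect
  (0.8), miRNA +1 / mRNA −2 tumor shifts (net target shift ≈ −1.2),
  target log HR = log 0.5, LD 0.5; the pipeline run twice must give
  identical checksums and the planted gene must be the funnel
  survivor.

## Numerical and interface conventions

* All file coordinates are 1-based inclusive (VCF, GFF3); any internal
  half-open arithmetic is invisible externally.
* Pairwise-complete handling everywhere: the union of missing
  genotype, expression and covariate entries is dropped per test, and
  the n actually used is reported per result row.
* BH is the adjustment for every FDR threshold in the pipeline (the
  statsmodels implementation, checked against hand-computed step-up
  values in tests).
* Ties and ordering: scan output sorted by (p, |t| desc, ids); tag
  expansion by (chrom, pos, id); funnel genes processed sorted — all
  outputs are byte-deterministic and the pipeline manifest checksums
  them.
* Result files never contain timestamps; the run log does.

## Known limitations

Single-instrument MR cannot detect pleiotropy and the package
deliberately offers no multi-instrument meta-estimators (Egger,
weighted median) or colocalization. The Cox fitter is single-covariate
by design — the screen dichotomizes expression — and does not do model
selection, time-varying covariates or competing risks. The cis scan is
plain OLS without kinship or mixed-model adjustment, appropriate for
an ancestry-stratified cohort but not for strongly related samples.
Target-prediction scores are consumed as an annotation, never
recomputed.
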