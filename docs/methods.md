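# Methods

## Overview

The pipeline tests genes, not variants, for association between rare
variation and a binary trait in a small case-control sequencing
cohort.  Its stages are: (1) ingest a VCF, a refFlat-style gene-model
table and a phenotype table; (2) filter to rare variants; (3) impute
residual missing genotypes; (4) group variants into genes; (5)
collapse each gene's singletons into a binary supervariant; (6) test
each gene with three permutation-based statistics under a two-step
schedule; (7) characterize significant supervariants with exact tests,
region stratification and principal-component adjustment.

## Definitions and preprocessing

**Dosage matrix.** Genotypes are alternate-allele counts 0/1/2 with a
missing code; only bi-allelic SNVs are loaded (multi-allelic and indel
lines are skipped and logged).

**Phenotype.** A longitudinal binary trait over up to four visits is
collapsed to "case iff affected at any non-missing visit"; samples
with no visit are dropped.

**Filters.** A variant is retained when it is (a) absent from a
user-supplied known-site list (matched by `chrom:pos:ref:alt` key or
rsID — the stand-in for a dbSNP-membership test, with no bundled
database), (b) has minor allele frequency ≤ 1% among non-missing
genotypes, and (c) has genotype missing rate ≤ 5%.  Removal uses
strict inequalities, so MAF exactly 1% and missingness exactly 5% are
retained.  MAF is computed before imputation.  The filter report
counts each removed variant once at the first rule that removes it
(known → MAF → missingness); the retained set is order-independent.

**Imputation.** Each missing genotype is resampled uniformly, with
replacement, from the variant's non-missing genotypes.  This
preserves the per-variant allele-frequency expectation and is
reproducible from a seed.

**Gene grouping.** A variant joins every gene whose transcript
interval `[txStart, txEnd]` (1-based, inclusive on both ends)
contains its position; variants in no gene are dropped, as are genes
with no variants.  Overlapping genes therefore share variants, and
their tests are not independent — relevant when choosing the
multiple-testing denominator.  Gene *length* is defined as
`txEnd − txStart` (the convention under which a transcript printed as
chr9:135,136,827-135,230,372 spans 93,545 bp).

## Singleton collapsing

A **singleton** is a variant whose minor allele appears exactly once
across all samples — a single heterozygote.  A lone homozygote
carries two copies and does not qualify; the folded count is used, so
a variant minor in the reference direction is handled symmetrically.
Singleton status is determined on the full cohort (cases and controls
jointly) before any phenotype information is used, which is required
for validity of the permutation null.

The gene's **supervariant** is `X_i = 1` iff sample `i` has dosage
≥ 1 at one or more of the gene's singletons.  It is invariant to
variant ordering and duplication of non-singleton columns, and the
number of carriers is at most the number of singletons, with equality
iff all singletons sit in distinct samples.

**Region stratification.** Each in-gene position is classified CDS
(inside an exon and inside the CDS interval), UTR (exonic, outside
the CDS; both UTR sides and non-coding exons collapse here) or intron
(everything else); the three classes partition the transcript.
Region subsets inherit the gene-level singleton list — a singleton of
the gene remains a singleton of the subset — so region singleton
counts partition the gene's count.

## Association tests

The per-gene feature matrix is the dosages of the non-singleton rare
variants plus the binary supervariant column (collapsing precedes
testing; a flag preserves the uncollapsed alternative).  Constant
columns are dropped; a gene with no remaining features is untestable.

- **SSU (linear-kernel score).** `U = F'(y − ȳ)`, statistic
  `S = U'U` with flat weights.  This is the quality-unweighted
  multivariate score association test and coincides with
  linear-kernel SKAT.
- **C-alpha.** With `n_i` the variant's total minor-allele count,
  `y_i` its count in cases, and `p₀` the case fraction,
  `T = Σ_i [(y_i − n_i p₀)² − n_i p₀ (1 − p₀)]`.  Note that with flat
  weights `T` equals `S` minus a label-invariant constant, so the two
  tests produce identical permutation p-values — the equivalence that
  motivates treating them as one family.  Both are retained for
  interface fidelity.
- **CMC.** Features are binned by allele count — default two bins,
  {count = 1} (the supervariant joins this bin, as it aggregates
  singletons) and {count ≥ 2} — each bin contributing a per-sample
  carrier indicator; the indicators are compared between cases and
  controls with Hotelling's T² using the pooled covariance and a
  Moore-Penrose pseudo-inverse (singleton-heavy matrices are
  routinely rank-deficient).  The bin edges are configurable because
  no canonical choice exists.

**Permutation.** Phenotype labels are shuffled uniformly; the
statistic's direction is "large = associated" for all three tests;
`b` counts permuted statistics ≥ the observed one (ties count against
significance, with a 1e-9 relative guard so that exact float ties
compare as ties), and `p = b/B`, displayed `< 1/B` when `b = 0`.  The
conservative `(b+1)/(B+1)` estimate is also available.  All three
methods share one permutation stream per (gene, stage), making them
comparable and the scan cheaper; streams are seeded per (gene, stage)
so any execution order or parallel schedule gives identical results.
The observed statistic is computed through the same vectorized code
path as the permuted ones, so ties are exact.

**Two-step schedule.** Every gene is screened at B₁ = 1000; genes
with estimated p < 0.001 for any method are re-tested at B₂ = 10⁶ for
all methods.  Genes whose final p falls below the Bonferroni
threshold `α / n_genes` (denominator configurable; 10,000 is the
conventional round number for a genome-wide gene-based scan) are
flagged significant.

**Exact tests.** The supervariant's 2×2 carrier table is tested with
the two-sided Fisher exact test ("probabilities ≤ observed" rule).
The odds ratio is the conditional MLE under Fisher's noncentral
hypergeometric distribution (the root of `E[X | ψ] = a`), and the 95%
CI inverts the one-sided exact tail tests at 0.025 per side.  These
are the conventions of standard exact-test software.  One caveat
found while validating: R's `fisher.test` computes the CI bounds by
root-finding at a loose default tolerance on the reciprocal-odds
scale, so its printed bounds can differ from the exact roots by a few
hundredths (e.g. 27.433 printed where the exact root is 27.448).
`fisher_exact_2x2` returns the exact roots; `reconstruct_table`
therefore matches printed CI targets to 1% relative rather than
digit-exact when enumerating candidate tables behind a published
p/OR/CI summary.

**Per-variant testing.** Each variant is dichotomized to carrier
(dosage ≥ 1) versus non-carrier and Fisher-tested individually;
variants sharing a carrier split share one evaluation.  With 64/39
margins and at most 2 minor-allele copies per rare variant, the
smallest achievable two-sided p is ≈ 0.141 (both copies in controls),
which is why per-variant testing is structurally powerless here.

## Stratification adjustment

Principal components are computed from a uniform random sample of
common variants (no missing genotypes, MAF > 0.1 strictly; if fewer
qualify than requested, all are used with a warning).  Genotypes are
z-scaled per variant (zero-variance columns dropped) — the simpler of
the two standard scalings, exposed in config; scores are SVD
projections with the sign fixed by the largest-magnitude loading.
The supervariant is then re-tested by maximum-likelihood logistic
regression of case status on `[X, PC1..PCk]` with per-coefficient
Wald p-values (matching the practice of reading off covariate
significance per component).  Perfect or quasi-separation is detected
via non-convergence or exploding standard errors and handled by a
Firth (Jeffreys-penalized) fit, labeled in the result.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes;
defaults are 64 cases / 39 controls and one signal gene with 380 rare
variants, 135 of them singletons, spanning 93,545 bp over 26 exons
with 8,034 coding bases and variant placement weighted 14 : 6 : 360
across CDS : UTR : intron.

- **Signal gene (retrospective carrier model).** Supervariant carrier
  status is drawn per sample: probability `q1` in cases, `q0` in
  controls (default 0.2), with `q1/(1−q1) = OR · q0/(1−q0)` and
  default OR = 8.8.  Each designated carrier receives at least one
  singleton; remaining singletons are spread uniformly over carriers.
  A designation incompatible with the singleton count (more carriers
  than singletons, or zero carriers) is redrawn; persistent failure
  raises a configuration error.  Retrospective sampling is used
  because the estimand is the carrier odds ratio — the quantity the
  Fisher analysis reports.
- **Null genes.** Each singleton lands on a uniformly random sample,
  independent of phenotype — the natural exchangeable model and one
  that stays feasible for genes with few singletons.
- **Non-singleton rare variants** place `2..floor(0.01·2n)` minor-
  allele copies on distinct chromosomes chosen uniformly (for
  n = 103 this forces exactly 2 copies), guaranteeing the count ≥ 2
  and MAF ≤ 1% exactly rather than by rejection.
- **Confounding mode.** Samples split into two subpopulations;
  subpopulation B has a higher case fraction (labels drawn
  conditional on case status by Bayes' rule from the per-subpopulation
  case fractions).  One divergence parameter `δ` acts twice: rare
  carriers are placed with per-sample weights `1 ± δ`, and common-
  variant frequencies diverge by a Balding-Nichols model with
  Fst = δ.  This yields genuinely inflated unadjusted tests and
  principal components that actually carry the structure.
- **Common background variants** (optional, default off) have
  ancestral MAF uniform on (0.15, 0.45) and live on their own
  chromosome outside every gene, so the rare-variant filter removes
  them from association testing while the PCA selector can use them.

What the generator does **not** emulate: linkage disequilibrium,
relatedness, sequencing error and genotype quality, multi-allelic
sites, indels, and any realistic gene-length or site-frequency
distribution beyond the configured shapes.  Passing tests therefore
demonstrate the statistical machinery — calibration, power ordering,
confounding correction — under idealized genotypes, not performance
on real sequencing data.

## Numerical choices

- Exceedance counting uses ≥ with a 1e-9 relative tie guard
  (conservative).
- Hotelling T² uses `numpy.linalg.pinv`; duplicated bins give the
  same statistic as their deduplicated counterpart.
- Odds-ratio and CI root-finding runs on the log-odds axis with
  bracket expansion; empty-cell tables return 0 or ∞ with one-sided
  intervals.
- All randomness flows through `numpy.random.SeedSequence` hierarchies
  keyed by (seed, gene index, stage), so reruns are byte-identical
  and stages can be tested in isolation.

## Problem sizes used in validation

The validation suite runs null calibration on 500 null genes of 45
variants (15 singletons) at B = 200 permutations; power comparisons
on 60 replicate signal cohorts; and confounding checks on 40
replicate confounded cohorts of 10 null genes each with 5 principal
components from ~200-300 common variants.  These sizes give binomial
standard errors small enough for the qualitative claims being checked
while keeping the whole suite fast.

## Known limitations

- The asymptotic p-value routes (Davies/Liu for variance-component
  tests, normal approximation for C-alpha) are deliberately absent;
  significance is permutation-only.
- Covariates enter only through the post-hoc logistic adjustment, not
  inside the permutation engine.
- One transcript model per gene; no isoform handling, splice classes
  or promoter annotation.
- With the default two CMC bins and very small genes the statistic is
  coarsely discrete; its permutation p-values are mildly conservative.
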