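# Methods

This note documents the statistical models, numerical choices and synthetic
data conditions behind `gxewas`, at the level a user of the package needs to
interpret its output.

## Study design being modeled

The pipeline reproduces the shape of a two-cohort / three-dataset
birth-cohort analysis: cord-blood DNAm beta values measured on two array
generations, best-guess imputed genotypes, a harmonized cumulative prenatal
stress score, and three association models per sub-cohort (environment-only,
genotype-only, genotype-by-environment), meta-analyzed with fixed effects.
Individual-level data of that kind are access-restricted, so the package
ships a generator that emulates the design and plants known effects; every
power or recovery statement in the test suite is therefore a statement about
this synthetic world, not about any real cohort.

## Cumulative stress score

Raw items are dichotomized to risk indicators by per-item config rules
(threshold + direction, identity for binary items); every item belongs to
exactly one of four domains (life events, contextual, personal,
interpersonal). Subjects missing strictly more than 50% of items are
excluded. Remaining gaps are filled by single-imputation predictive mean
matching run as chained equations: each incomplete item is regressed on all
other items over its observed rows, the 5 observed rows nearest in predicted
value form the donor pool (ties to the lowest row index), and one donor's
observed value is copied at random. We run 60 cycles by default; the
literature this follows says "60 iterations" without specifying cycles
versus draws, and we read it as cycles. Imputed values are always observed
donor values, hence binary.

Domain scores are within-domain means (each in [0, 1]); the total is their
sum (in [0, 4]). Totals are z-standardized within cohort (n−1 denominator)
and then winsorized at Q1 − 3·IQR / Q3 + 3·IQR. Standardize-before-winsorize
is a deliberate ordering choice: the winsorization bounds are defined on the
standardized score's quantiles. Quantiles use linear interpolation between
order statistics (numpy default) — stated because winsorization bounds are
sensitive to the quantile rule at small n.

## Genotype QC

SNP filters run in a fixed, logged order: indel/multi-allelic pattern →
call rate < 95% → exact Hardy–Weinberg p < 1e-7 → MAF < 5% → imputation info
score below a per-cohort floor. The order is a package convention (the
filters themselves are standard); logged per-filter drop counts make it
auditable. MAF and HWE are computed on non-missing calls after sample
exclusions. The HWE test is the exact conditional test: given allele counts,
all heterozygote counts of matching parity are enumerated and probabilities
≤ the observed one are summed (log-gamma arithmetic, relative tie tolerance
1e-12).

Cryptic relatedness (externally supplied IBD estimates > 0.15) is resolved
greedily from the highest-IBD pair down, keeping the member with more
complete data, ties broken by a seeded draw; a post-condition guarantees no
retained pair stays flagged. LD pruning follows the window/step/VIF
convention (50 SNPs, step 5, VIF ≤ 2) on additive dosages: within each
window the highest-VIF SNP is dropped iteratively (VIF from regressing each
dosage on the other retained dosages; R² ≥ 1 − 1e-12 counts as infinite;
ties drop the later position). Dominant coding contrasts carriers of ≥1
minor allele against homozygous major, with the minor allele defined in the
designated reference (largest) cohort; allele labels are harmonized by
matching, swapped labels flip the coding, and strand-ambiguous A/T and C/G
SNPs are dropped rather than guessed.

## Methylation preparation

Probes pass a variability rule (top-K by MAD or a MAD floor — the original
variability pre-selection relied on an external study and is irreproducible
here, so the rule is configurable and defaults to keeping everything), then
cross-reactive probes are removed, then probes are restricted to the set
shared across array types; counts at each step partition the input. Betas of
each retained CpG are winsorized with the same 3·IQR rule as the stress
score. Winsorization is applied after filtering; the reverse order would
only change MAD values marginally.

## Scan engine

All three models are ordinary least squares with DNAm beta values as the
outcome (not M-values — matching the convention of the studies this package
serves) and covariates C = sex, 5 genetic PCs, 7 cell proportions, batch
dummies. C is cleaned jointly with the intercept by pivoted-QR rank
detection (tolerance 1e-8 relative to the leading diagonal); cell
proportions summing to one and exhaustive dummy blocks are handled this way
rather than by convention-specific drops.

The GxE model includes both main effects alongside the interaction — the
interaction test is only valid with them present. Speed comes from the
Frisch–Waugh–Lovell theorem: M and the tested regressors are projected off
the nuisance columns once per design (QR-based), after which the per-pair
fit is a 1×1 (E, G models) or 2×2 (GxE) normal-equation solve whose cross
products are computed for all SNPs × all CpGs as two matrix products.
Missing genotypes are handled exactly, not approximately: SNPs are grouped
by missingness pattern and the projection is recomputed on each pattern's
complete cases. Degrees of freedom are n − (number of estimated
coefficients); p-values are two-sided from the t distribution.

ΔadjR² is the adjusted-R² increment of the tested term: adjR²(full) −
adjR²(full without the term), both against the total sum of squares about
the CpG mean. This is one of several readings of "adjusted R² of the term";
it is the one implemented and tested.

Degenerate cases are flagged, never silently fit: zero-variance CpGs,
genotypes monomorphic after complete-case restriction, and interaction
columns collinear with the main effects each produce a flagged record with
NaN statistics. A naive per-pair OLS oracle (explicit normal equations) is
part of the public API and the test suite verifies every scan statistic
against it to 1e-8 relative error on random designs with and without
missing genotypes, as well as chunk-size invariance.

## Meta-analysis and multiple testing

Fixed-effects inverse-variance weighting with normal (not t) combined
p-values, matching standard GWAS meta-analysis software behavior. Records
combine over however many cohorts report a usable estimate (k is recorded;
a require-all mode exists). Heterogeneity is Cochran's Q with
I² = max(0, (Q − (k−1))/Q)·100, undefined below k = 2; I² > 75 is the
conventional "considerable" flag. Direction strings carry +/−/? per cohort
in configured order. Bonferroni thresholds are α divided by (retained SNPs ×
retained CpGs) for pair models and by retained CpGs for the E model;
suggestive thresholds default to 5e-8 (pair models) and 1e-5 (E model).

## Annotation and enrichment

Distance between a SNP and CpG is the absolute difference of raw 1-based
positions, printed even for inter-chromosomal pairs (a reporting convention
kept on purpose); the cis flag additionally requires the same chromosome and
distance ≤ 1 Mb. Nearest genes come from a BED annotation (converted to
1-based inclusive), distance 0 inside a gene, ties to the lower start.
Fisher 2×2 tests are exact two-sided (tables no more probable than
observed); odds ratios are sample cross-product ratios with Haldane +0.5 on
any zero cell and Woolf log-OR 95% intervals — conditional-MLE odds ratios
from other software will differ on extreme tables. Gene-set
over-representation is a flat hypergeometric upper tail per set with a
resampling FWER: the adjusted p is the fraction of seeded same-size random
candidate sets whose minimum raw p across sets beats the observed set,
floored at the raw p so adjusted ≥ raw always holds. No GO-graph propagation
is performed; sets are taken as given.

## Follow-up

Domain decomposition refits a hit with all four domain scores in one model
(plus genotype and all four G×domain products for interaction hits), so each
domain's p is its unique contribution at α = 0.05. Mediation is the product
of coefficients on two linear fits: a from mediator ~ X + C, b and the
direct effect from Y ~ X + mediator + C, indirect = a·b with first-order
delta SE √(a²SE_b² + b²SE_a²) and a normal two-sided p; an optional seeded
percentile bootstrap replaces the delta interval. For complete-data linear
models this two-regression route coincides with joint ML path estimation.
The four mediators (smoking, alcohol, gestational age, birth weight) are
modeled separately, hence the 0.05/4 = 0.0125 significance threshold on the
indirect path. For interaction hits the exposure in the mediation model is
the centered G×E product with G and E retained as covariates — a package
convention, since mediation of an interaction effect has no single standard
parameterization. The pipeline mediates on the pooled sample with cohort
indicator covariates (batch dummies are cohort-specific and are replaced by
the cohort indicators there).

## Synthetic data generator

The generator's defaults are the study conditions of the test suite:

* **Cohorts** — 3 sub-cohorts of 1224 / 949 / 790 subjects with 25 / 12 / 20
  batches respectively.
* **Genotypes** — block LD via haplotype copy-with-probability (two
  haplotypes per subject; within a block each SNP shares the block allele
  frequency and copies the previous SNP's allele with probability 0.8, else
  redraws), which preserves marginal frequencies, hence HWE, while giving
  tunable adjacent-SNP r². MAF uniform on [0.05, 0.5]. SNP ids/positions are
  shared across cohorts; draws are cohort-independent.
* **Stress items** — ~50 binary items in domains of 17/13/10/10, generated
  from a probit threshold model with a shared per-subject liability
  (loading 0.5), domain prevalences proportioned 0.28/0.44/0.09/0.19 of the
  cohort target mean total score (0.36 / 0.44 / 0.51 per cohort), so the
  expected total equals the target exactly; item missingness is MCAR at 5%.
* **Methylation** — beta = inverse-logit of (probe baseline ~ N(0, 1.2²) +
  small sex/cell/batch effects + planted terms + N(0, 0.35²) noise).
  Logistic squashing keeps betas in (0,1) with no truncation artifacts.
* **Planted effects** — disjoint CpG sets for G-only, E-only, GxE and
  smoking-mediated effects; latent coefficients sized so each term's
  adjusted-R² increment is ≈0.02 (the magnitude of significant interaction
  terms in cohorts of this size), spread 0.5×–1.5× with alternating signs so
  recovery tests can rank them; genotype terms use the dominant coding the
  analysis applies. An optional per-cohort effect multiplier exercises the
  heterogeneity statistics.
* **Mediators** — smoking is a continuous score = 0.5·(standardized stress)
  + noise; the mediated CpGs receive the smoking effect on the latent scale,
  so their stress association exists only through smoking. Alcohol,
  gestational age (40 ± 1.5 weeks) and birth weight (3500 ± 500 g) have null
  stress paths.
* **Seeding** — one global seed fans out into fixed per-component,
  per-cohort child seeds (CRC-based tags, all < 2³¹), so outputs are
  byte-reproducible and components can be regenerated independently.

What the generator does **not** emulate: realistic chromatin or annotation
structure, population stratification beyond supplied PCs, array technical
artifacts, non-MCAR missingness, item-level measurement models, or LD decay
beyond the block-copy mechanism. Passing recovery tests therefore show the
*statistical machinery* is correct and calibrated under the assumed model;
they do not certify behavior on real arrays.

## Problem sizes and numerical conventions

Default simulated scans use 200 SNPs × 200 CpGs (40,000 pair tests per
model per cohort), a scale at which the full three-cohort pipeline, the
null-calibration scan and twenty mediation replicates all run in about a
minute on one core; the engine itself is O(n · SNPs · CpGs) in matrix
products and scales to much larger panels. Tolerances: scan-vs-oracle 1e-8
relative; rank detection 1e-8; HWE/Fisher tie tolerance 1e-12 relative;
collinearity of the interaction 2×2 system declared when its determinant
falls below 1e-12 of its diagonal product.

## Known limitations

Single imputation (no between-imputation variance); fixed-effects meta only
(no random effects or genomic control); no robust/sandwich errors or mixed
models; the emission threshold for pair-level records trades disk for
completeness and is off by default; nearest-gene and odds-ratio conventions
are stated rather than claimed identical to any specific annotation
toolchain.
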