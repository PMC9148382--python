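# Methods

This document describes the statistical and genetic methods implemented in
`twinrare`, module by module, with the conventions and formulas needed to
interpret every reported number.

## Study design being modelled

The pipeline reproduces the analysis pattern of a whole-genome sequencing
study of severe depression in a twin registry: a cohort of monozygotic (MZ)
and dizygotic (DZ) twin pairs plus unpaired singletons is sequenced; sites
pass population-level quality filters; analysis is restricted to
linkage-disequilibrium (LD) blocks around externally chosen lead variants;
rare non-silent variants are tested for association with four correlated
depression phenotypes, gene-collapsed with SKAT-O and singly with Fisher's
exact test; and the twin structure itself is verified from the genotypes
(identity-by-state, zygosity, relatedness) before constructing the analysis
cohorts.

## Genotype representation (`variant_qc`)

`GenotypeMatrix` stores samples x variants diploid alternate-allele dosages
in {0, 1, 2, -1} (-1 = missing) with two aligned per-entry layers: genotype
quality (GQ) and a per-sample-per-site pass flag (the VCF `FT` field, falling
back to the site `FILTER`).

**Site filters.** A site is kept when both population-level conditions hold
over its non-missing genotypes:

1. at least 90% of *carriers* (dosage 1 or 2) have a passing per-sample
   filter flag, and
2. at least 90% of genotyped samples have GQ >= 20.

A monomorphic site satisfies condition 1 vacuously. Sites with no genotyped
samples are dropped with reason "no data". Both thresholds are
configurable; filtering is idempotent and monotone in the thresholds.

**Allele bookkeeping.** `alt_allele_stats` reports the alternate-allele
count, total allele count (2 x genotyped samples), heterozygous and
homozygous carrier counts, and the alternate-allele frequency, excluding
missing genotypes from every denominator.

**Rare-variant inclusion.** A variant qualifies for association testing when
it is non-silent (stopgain, stoploss, frameshift, or nonsynonymous), its
*folded* minor-allele frequency is strictly below 0.05, and its minor-allele
count is at least 3, all computed on the analysis cohort of the current
contrast.

## Twin genomics (`twin_genomics`)

**Pairwise IBS.** For two samples, over co-genotyped sites, the number of
shared alleles at a site is `2 - |d_a - d_b|` for dosages d; the IBS percent
is 100 x shared / (2 x co-genotyped sites). MZ pairs are expected near 100%
(reduced only by somatic/technical discordance), DZ pairs intermediate,
unrelated pairs lowest.

**Zygosity verification** classifies each labelled pair as consistent or
inconsistent by comparing its IBS percentage to thresholds; thresholds can
be calibrated as midpoints between the observed class means (MZ / DZ /
unrelated), which must be strictly ordered.

**MZ discordant homozygotes.** Within an MZ pair, sites where one co-twin is
homozygous reference and the other homozygous alternate (both genotyped,
non-silent variant) are reported as discordance events; the "high-impact"
subset additionally requires CADD >= 20 and is de-duplicated by variant.

**Relatedness.** The coefficient of relatedness is twice the KING-robust
kinship estimate,

    r = 2 (N_AaAa - 2 N_AAaa) / (N_Aa(a) + N_Aa(b)),

over co-genotyped sites, where N_AaAa counts double-heterozygous sites,
N_AAaa opposite-homozygous sites, and N_Aa(.) heterozygous sites per sample.
The symmetrised denominator makes the estimate exactly symmetric. Expected
values: ~1 (MZ/duplicates), ~0.5 (DZ/full siblings), ~0 (unrelated). A
minimum co-genotyped site count (default 1000) is enforced because the
per-pair standard error scales with the inverse square root of the number of
*informative, independent* sites; rare variants and strong LD both inflate
it substantially.

**Cohort construction.** Two modes, both restricted to one ancestry label
(default EUR):

- *one-MZ-excluded*: one member of each complete MZ pair is dropped
  (keeping, in order of priority, a diagnosed member, then higher severity,
  then lexicographic sample ID); DZ pairs and singletons are kept whole.
- *unrelated-only*: additionally one member per DZ pair is dropped, and a
  supplied pairwise relatedness map is used to verify that no retained pair
  reaches the relatedness ceiling (default 0.1); offenders abort selection
  with an explicit list.

## LD-block regions (`region_mapper`)

**Genotype r².** The squared Pearson correlation of dosages over jointly
genotyped samples; monomorphic variants are rejected since the correlation
is undefined.

**Block borders.** From a lead variant, the scan extends outward in each
direction along the variant list (same chromosome only), stopping at the
first variant whose r² with the lead drops to or below the threshold
(default 0.2). The block is the contiguous run of variants with r² > 0.2 up
to the first break — a later rebound in r² does not re-extend the block.
The result is a `Region` (1-based, inclusive) carrying the lead's ID and
position.

**Interval mapping.** Gene models are half-open BED intervals; a gene
overlaps a region when their ranges intersect by at least one base. A
variant belongs to a gene by its annotation symbol when present, otherwise
by coordinates.

## Association testing (`association`)

**Phenotype contrasts.** Four case/control dichotomies of the correlated
depression variables: severity (severe vs not-severe), lifetime diagnosis,
early onset (onset age <= 30 vs late-onset or never depressed), and symptom
count (all nine vs fewer). Case and control rules are disjoint by
construction; bereavement-labelled samples and samples missing the tested
variable are excluded from the contrast.

**Covariates.** Principal components of the common-variant (folded MAF >=
0.05) dosage matrix, mean-imputed and scaled by sqrt(2p(1-p)); PCs 1-4 enter
the null model. If fewer components are computable on a sub-cohort the scan
degrades to the available number (down to an intercept-only null) with a
warning.

**Null model.** Logistic regression fitted by iteratively reweighted least
squares (IRLS, tolerance 1e-8); under separation a small ridge (1e-6) is
applied and flagged.

**SKAT-O.** For a gene's qualifying-variant dosage block G (missing entries
mean-imputed) with Beta(MAF; 1, 25) weights W, the score vector is
s = (GW)' (y - mu). The family of statistics

    Q_rho = (1 - rho) * ||s||^2 + rho * (1's)^2,   rho in {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}

interpolates between the variance-component SKAT statistic (rho = 0) and the
squared weighted burden score (rho = 1). Each Q_rho is a quadratic form in
the residuals; its null distribution is the weighted chi-squared mixture
with eigenvalues of R_rho^{1/2} A R_rho^{1/2}, where A = (GW)' P0 (GW) and
P0 is the projection-adjusted variance matrix of the logistic null. The
omnibus p-value of min-p over the grid follows the standard SKAT-O
construction: per-rho quantiles at the observed minimum p, a conditioning
decomposition of Q_rho given the burden direction, and a one-dimensional
integral over the burden chi-squared evaluated with Gauss-Legendre
quadrature and a Chebyshev interpolant of the kernel mixture CDF. A single
variant (or rank-1 kernel) makes every Q_rho identical, so min-p is returned
directly.

**Quadratic-form tail probabilities.** `quadform_pvalue` inverts the
characteristic function (Imhof's method): the integral head is evaluated by
adaptive quadrature on [0, u0] with u0 = min(16 pi / q, 32 / lambda_max),
and the oscillatory tail by QUADPACK's QAWF Fourier-weighted rule applied to
the sine/cosine decomposition of the integrand. Closed chi-squared forms are
used when all eigenvalues are equal, and the Liu moment-matching
approximation serves as fallback and as the deep-tail (p < 1e-14) shortcut,
since the inversion's absolute accuracy target (1e-9) cannot resolve such
tails.

**Single-variant tests.** Fisher's exact two-sided p-value on the 2x2
allelic table (case/control x alt/ref alleles), using the
minimum-likelihood definition: the sum of hypergeometric probabilities not
exceeding that of the observed table (relative tie tolerance 1e-11). The
pmf is computed by an lgamma-seeded exact-ratio recurrence across the
support. Odds ratios use the cross-product with a Wald 95% CI on the log
scale; if any cell is zero the Haldane-Anscombe 0.5 correction is applied
and flagged.

**Multiple testing.** Bonferroni within each contrast x unit-kind family:
p_adj = min(1, n_tests x p). Results are sorted by raw p within family.

## Synthetic cohort (`synthetic_cohort`)

**Haplotypes.** Variants are partitioned into contiguous blocks. Each block
has a baseline allele frequency drawn from a configurable spectrum (default
rare-skewed: 0.002 + 0.498 x Beta(0.25, 1)) and a target within-block
allelic r². A haplotype draws one block *tag* allele, and each variant
copies the tag with probability m or draws independently, giving expected
pairwise allelic r² = m^4 inside the block (the target) and 0 between
blocks. Two subpopulations diverge by a Balding-Nichols Beta draw around
the base frequency with the configured Fst.

**Twins.** MZ pairs share one diploid genotype, perturbed by a per-site
somatic discordance (default 1e-4). DZ twins inherit one maternal and one
paternal haplotype independently per block from four parental haplotypes
(0/1/2 shared copies with probability 1/4, 1/2, 1/4 — expected relatedness
0.5). Singletons draw two haplotypes.

**Causal variant.** Optionally one variant is planted: `causal_af` draws it
as an independent Bernoulli per haplotype (decoupling its marginal frequency
from its block), and its liability coefficient is calibrated jointly with
the diagnosis threshold (fixed-point over two Brent solves) so that the
model reproduces the configured population prevalence *and* the configured
allelic odds ratio exactly in expectation.

**Phenotypes.** An ACE-style liability model: liability = beta x dosage +
shared pair term (variance 0.4; correlation 1 in MZ, 0.5 in DZ pairs) +
unique noise (variance 0.6). Thresholding yields the lifetime diagnosis at
the target prevalence (~10.8%); severity grades, nine-symptom status and
early onset are assigned among the diagnosed in descending liability order
at their target marginal frequencies, making all four variables mutually
correlated; bereavement labels are sprinkled among the non-depressed.

**Quality layers and serialization.** Per-entry GQ and pass flags include a
small fraction of "bad" sites with elevated failure rates, plus uniform
genotype missingness. Cohorts serialize to VCF (GT:GQ:FT), phenotype and
annotation TSVs, region/gene BED files, and a ground-truth JSON, and round
trip exactly.

## Verification strategy

The test suite checks the statistical core against independent oracles:
exhaustive exact-integer enumeration for Fisher's test (every table with
total <= 200, tolerance 1e-12), chi-squared closed forms and 10^7-draw Monte
Carlo for the quadratic-form tail probabilities, an independently coded
burden score test for the SKAT-O rho = 1 branch, empirical type-I error
calibration for the omnibus test, and generator ground truth for the
twin-structure, LD-border and end-to-end power properties. Randomized
designs were dimensioned on pilot seeds disjoint from the seeds used in the
tests themselves.
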