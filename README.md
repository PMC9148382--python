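# twinrare

Rare-variant association and twin-genome concordance pipeline for
depression-style case/control studies in twin cohorts.

## The scientific problem

Severe depression is heritable, but common-variant studies explain little of
that heritability in small, deeply phenotyped cohorts. One complementary
design sequences the whole genomes of a twin registry cohort and asks two
questions:

1. **Association.** Within LD blocks surrounding previously implicated lead
   variants, are rare (MAF < 0.05), non-silent variants — individually or
   collapsed per gene — associated with depression phenotypes (lifetime
   diagnosis, severity, early onset, symptom count)?
2. **Twin concordance.** Do the genomes themselves confirm the registry's
   twin structure — monozygotic (MZ) pairs nearly identical by state,
   dizygotic (DZ) pairs at ~50% relatedness — and do MZ co-twins harbour
   any discordant high-impact genotypes?

`twinrare` implements this full analysis as a reusable, tested pipeline:
site/variant QC, LD-block delineation (r² > 0.2 around lead variants),
gene-collapsed SKAT-O with genotype principal components as covariates,
single-variant Fisher's exact tests with odds ratios and Wald intervals,
Bonferroni correction per test family, pairwise IBS / KING-robust
relatedness / zygosity verification, and the one-MZ-excluded and
unrelated-only cohort-construction rules. Because the original cohort data
are access-restricted, a synthetic twin-cohort generator (LD-blocked
haplotypes, two-ancestry stratification, ACE liability phenotypes, MZ/DZ
genetic sharing, per-sample quality layers) drives the whole pipeline with
no external data. See [docs/methods.md](docs/methods.md) for the formulas
and conventions.

## Worked example

### Single-variant statistics

The allelic 2x2 tables reported by the scan can be computed directly. For a
case/control table `[[case alt, case ref], [ctrl alt, ctrl ref]]`:

```python
from twinrare.association import fisher_exact_2x2, odds_ratio_ci

r = odds_ratio_ci([[7, 87], [19, 1995]])
print(f"OR = {r.odds_ratio:.2f}, 95% CI ({r.ci_low:.2f}, {r.ci_high:.2f}), "
      f"Fisher p = {fisher_exact_2x2([[7, 87], [19, 1995]]):.2e}")
```

prints

```
OR = 8.45, 95% CI (3.46, 20.63), Fisher p = 9.20e-05
```

### End-to-end: recover a planted causal gene

Simulate a cohort with one causal variant (allelic odds ratio 8 at allele
frequency 0.01, calibrated exactly through the liability model), then run
the gene-collapsed SKAT-O scan:

```python
import numpy as np
from twinrare.association import run_scan, standard_contrasts
from twinrare.synthetic_cohort import SimulationConfig, simulate_cohort
from twinrare.twin_genomics import select_analysis_cohort

cfg = SimulationConfig(
    n_mz_pairs=0, n_dz_pairs=0, n_singletons=1000,
    n_variants=300, n_blocks=10,
    ancestry_fractions=(1.0, 0.0),
    causal_variant_index=155, causal_af=0.01,
    causal_log_odds=float(np.log(8.0)),   # target allelic OR 8
    seed=7,
)
cohort = simulate_cohort(cfg)
kept = select_analysis_cohort(cohort.samples)
rows = [cohort.genotypes.sample_index(s.sample_id) for s in kept]
contrast = [c for c in standard_contrasts() if c.name == "lifetime_dx"]
results = run_scan(
    cohort.genotypes.subset_samples(rows), cohort.variants, kept,
    cohort.regions, cohort.gene_models, contrast, unit_kind="gene",
)
print(f"planted causal gene: {cohort.truth.causal_gene}")
for r in results[:3]:
    print(f"{r.unit_id}: n_variants={r.n_variants} p={r.p_raw:.3g} "
          f"p_adj={r.p_adjusted:.3g} (n_tests={r.n_tests})")
```

prints

```
planted causal gene: GENE05A
GENE05A: n_variants=1 p=1.09e-05 p_adj=7.65e-05 (n_tests=7)
GENE07A: n_variants=1 p=0.455 p_adj=1 (n_tests=7)
GENE06A: n_variants=3 p=0.604 p_adj=1 (n_tests=7)
```

### Command line

The same stages are driven by the `twinrare` CLI (flat `key = value` config
files optional; flags override):

```sh
twinrare simulate --n-mz-pairs 60 --n-dz-pairs 40 --n-singletons 40 \
    --n-variants 400 --n-blocks 10 --seed 42 --output-dir cohort
twinrare run --vcf cohort/genotypes.vcf --phenotypes cohort/phenotypes.tsv \
    --annotations cohort/annotations.tsv --regions cohort/regions.bed \
    --gene-models cohort/gene_models.bed --output-dir results
```

logs

```
INFO twinrare: site QC: 386 of 400 sites kept (pass_min=0.90 gq>=20 gq_min=0.90)
INFO twinrare: concordance: 120 pairs written
INFO twinrare: regions: 10 loaded from cohort/regions.bed
INFO twinrare: cohort (one-mz-excluded, EUR): 169 of 240 samples
INFO twinrare: association: 56 result rows
```

and writes `qc_report.tsv`, `concordance.tsv` (per-pair IBS + zygosity
consistency), `cohort.tsv` (membership and exclusion reasons),
`associations.tsv` (one row per tested unit with p, Bonferroni-adjusted p,
odds ratio, CI and allelic counts) and `summary.tsv` (tests per family).
Subcommands `qc`, `concordance`, `regions` (`--lead-ids`) and `associate`
run individual stages.

## Modules

| Module | Contents |
| --- | --- |
| `twinrare.variant_qc` | genotype matrix, site filters, allele bookkeeping, rare/non-silent inclusion rules, VCF reader |
| `twinrare.twin_genomics` | pairwise IBS, zygosity verification, MZ discordant homozygotes, KING-robust relatedness, cohort construction |
| `twinrare.region_mapper` | genotype r², LD-block border scan, gene/region interval mapping, BED I/O |
| `twinrare.association` | contrasts, genotype PCs, logistic null, SKAT-O with Imhof/Liu quadratic-form p-values, Fisher/OR/Bonferroni, scan driver |
| `twinrare.synthetic_cohort` | seeded twin-cohort generator with planted causal effects and ground truth |
| `twinrare.cli` | `twinrare` command-line entry point |

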