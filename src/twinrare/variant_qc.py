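"""Site-level genotype QC and variant-inclusion rules.

A site survives QC when (1) at least ``pass_min`` of the non-missing carriers
of an alternate allele have a per-sample PASS filter, and (2) at least
``gq_min`` of the non-missing genotyped samples have genotype quality of at
least ``gq_threshold``.  Downstream association testing additionally restricts
to non-silent variants (nonsynonymous, frameshift, stopgain, stoploss) that
are rare (folded MAF below ``maf_max``) but observed at least ``mac_min``
times in the analysis cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "VariantRecord",
    "SiteFilterResult",
    "AltAlleleStats",
    "NONSILENT_CLASSES",
    "site_filter",
    "is_nonsilent",
    "alt_allele_stats",
    "rare_variant_filter",
    "read_vcf",
]

#: ANNOVAR-style functional classes counted as non-silent.
NONSILENT_CLASSES = frozenset({"nonsynonymous", "frameshift", "stopgain", "stoploss"})

MISSING = -1  # sentinel for missing dosage / GQ entries


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid dosages with per-entry quality metadata.

    Attributes
    ----------
    dosage
        ``(n_samples, n_variants)`` int array in {0, 1, 2}; ``-1`` marks a
        missing genotype.  Missing entries are excluded from every count and
        proportion computed downstream.
    gq
        Genotype qualities, same shape; ``-1`` marks missing.
    sample_pass
        Per-entry boolean, True where the per-sample filter (VCF ``FT``) is
        PASS.
    samples
        Sample identifiers, one per row.
    variant_ids
        Variant identifiers, one per column.
    """

    dosage: np.ndarray
    gq: np.ndarray
    sample_pass: np.ndarray
    samples: list = field(default_factory=list)
    variant_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        self.gq = np.asarray(self.gq)
        self.sample_pass = np.asarray(self.sample_pass, dtype=bool)
        if not (self.dosage.shape == self.gq.shape == self.sample_pass.shape):
            raise ValueError("dosage, gq and sample_pass layers must share one shape")
        if self.dosage.ndim != 2:
            raise ValueError("genotype layers must be 2-dimensional (samples x variants)")
        if self.samples and len(self.samples) != self.dosage.shape[0]:
            raise ValueError("sample list length does not match dosage rows")
        if self.variant_ids and len(self.variant_ids) != self.dosage.shape[1]:
            raise ValueError("variant-id list length does not match dosage columns")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not present") from None

    def subset_samples(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            dosage=self.dosage[rows],
            gq=self.gq[rows],
            sample_pass=self.sample_pass[rows],
            samples=[self.samples[i] for i in rows] if self.samples else [],
            variant_ids=list(self.variant_ids),
        )

    def subset_variants(self, cols: Sequence[int]) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(
            dosage=self.dosage[:, cols],
            gq=self.gq[:, cols],
            sample_pass=self.sample_pass[:, cols],
            samples=list(self.samples),
            variant_ids=[self.variant_ids[i] for i in cols] if self.variant_ids else [],
        )


@dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic site with ANNOVAR-like annotation."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_id: str = "."
    gene: Optional[str] = None
    func_class: str = "other"
    cadd: Optional[float] = None
    ref_pop_af: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based coordinates)")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


class SiteFilterResult(NamedTuple):
    keep: bool
    carrier_pass_proportion: float
    gq_proportion: float
    reason: str


class AltAlleleStats(NamedTuple):
    alt_count: int
    total_alleles: int
    het_carriers: int
    hom_carriers: int
    frequency: float


def site_filter(
    matrix: GenotypeMatrix,
    variant_index: int,
    pass_min: float = 0.9,
    gq_threshold: int = 20,
    gq_min: float = 0.9,
) -> SiteFilterResult:
    """Population-level site filter.

    Keeps a site iff the proportion of non-missing alternate-allele carriers
    whose per-sample filter is PASS is at least ``pass_min`` AND the
    proportion of non-missing genotyped samples with GQ >= ``gq_threshold``
    is at least ``gq_min``.  A monomorphic site (no carriers) satisfies the
    carrier condition vacuously: the condition constrains carriers only, and
    such sites are removed later by the minor-allele-count rule anyway.
    """
    dose = matrix.dosage[:, variant_index]
    gq = matrix.gq[:, variant_index]
    ft = matrix.sample_pass[:, variant_index]
    genotyped = dose != MISSING
    n_genotyped = int(genotyped.sum())
    if n_genotyped == 0:
        return SiteFilterResult(False, float("nan"), float("nan"), "no data")

    carriers = genotyped & (dose >= 1)
    n_carriers = int(carriers.sum())
    if n_carriers == 0:
        pass_prop = 1.0  # vacuous: empty carrier set
    else:
        pass_prop = float(ft[carriers].sum()) / n_carriers

    # Missing GQ on a genotyped sample counts as failing the GQ threshold.
    gq_prop = float(((gq != MISSING) & (gq >= gq_threshold) & genotyped).sum()) / n_genotyped

    keep = pass_prop >= pass_min and gq_prop >= gq_min
    if keep:
        reason = "pass"
    elif pass_prop < pass_min:
        reason = "carrier PASS proportion below threshold"
    else:
        reason = "GQ proportion below threshold"
    return SiteFilterResult(keep, pass_prop, gq_prop, reason)


def is_nonsilent(variant: VariantRecord) -> bool:
    """True iff the functional class is one of the non-silent coding classes."""
    return variant.func_class in NONSILENT_CLASSES


def alt_allele_stats(matrix: GenotypeMatrix, variant_index: int) -> AltAlleleStats:
    """Alternate-allele bookkeeping over non-missing genotypes at one site."""
    dose = matrix.dosage[:, variant_index]
    genotyped = dose != MISSING
    n = int(genotyped.sum())
    if n == 0:
        raise ValueError("no genotypes at variant index %d" % variant_index)
    het = int((dose[genotyped] == 1).sum())
    hom = int((dose[genotyped] == 2).sum())
    total = 2 * n
    alt = het + 2 * hom
    return AltAlleleStats(alt, total, het, hom, alt / total)


def rare_variant_filter(
    stats: AltAlleleStats, maf_max: float = 0.05, mac_min: int = 3
) -> bool:
    """Inclusion rule on the analysis cohort: folded MAF < ``maf_max`` (strict)
    and minor-allele count >= ``mac_min`` (inclusive)."""
    mac = min(stats.alt_count, stats.total_alleles - stats.alt_count)
    maf = mac / stats.total_alleles if stats.total_alleles else 0.0
    return maf < maf_max and mac >= mac_min


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read a multi-sample VCF (GT/GQ and optional per-sample FT) into a
    :class:`GenotypeMatrix` plus bare :class:`VariantRecord` objects.

    When the ``FT`` FORMAT field is absent at a site, the site-level FILTER
    column stands in for every sample.  Annotation fields (gene, functional
    class, CADD) are not read here; they come from the annotation table.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    dosages, gqs, fts, records = [], [], [], []
    for v in vcf:
        gts = v.genotypes  # list of [a, b, phased]
        dose = np.full(n, MISSING, dtype=np.int16)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                dose[i] = a + b
        gq_arr = v.format("GQ")
        if gq_arr is None:
            gq_col = np.full(n, MISSING, dtype=np.int32)
        else:
            gq_col = gq_arr.reshape(n).astype(np.int64)
            gq_col = np.where((gq_col < 0) | (gq_col > 10**6), MISSING, gq_col)
        ft_arr = v.format("FT")
        if ft_arr is None:
            site_pass = (v.FILTER is None) or (v.FILTER == "PASS")
            ft_col = np.full(n, site_pass, dtype=bool)
        else:
            ft_col = np.array(
                [str(x) in ("PASS", "b'PASS'") for x in np.asarray(ft_arr).reshape(-1)[:n]],
                dtype=bool,
            )
        dosages.append(dose)
        gqs.append(gq_col)
        fts.append(ft_col)
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=int(v.POS),
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else "N",
                variant_id=v.ID or ".",
            )
        )
    if not records:
        matrix = GenotypeMatrix(
            dosage=np.zeros((n, 0), dtype=np.int16),
            gq=np.zeros((n, 0), dtype=np.int32),
            sample_pass=np.zeros((n, 0), dtype=bool),
            samples=samples,
            variant_ids=[],
        )
        return matrix, []
    matrix = GenotypeMatrix(
        dosage=np.stack(dosages, axis=1),
        gq=np.stack(gqs, axis=1),
        sample_pass=np.stack(fts, axis=1),
        samples=samples,
        variant_ids=[r.variant_id for r in records],
    )
    return matrix, records


def apply_site_filters(
    matrix: GenotypeMatrix,
    pass_min: float = 0.9,
    gq_threshold: int = 20,
    gq_min: float = 0.9,
) -> tuple[np.ndarray, list[SiteFilterResult]]:
    """Run :func:`site_filter` across all sites; returns (kept indices, results)."""
    results = [
        site_filter(matrix, j, pass_min=pass_min, gq_threshold=gq_threshold, gq_min=gq_min)
        for j in range(matrix.n_variants)
    ]
    kept = np.array([j for j, r in enumerate(results) if r.keep], dtype=int)
    return kept, results
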