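"""LD-block region delineation around lead variants, and gene/variant lookup.

A region is the contiguous breadth of the r-squared peak around a lead
variant: scanning outward along the ordered variants, the border in each
direction is the last consecutive variant whose squared dosage correlation
with the lead exceeds ``r2_min``; the scan stops at the first variant at or
below the threshold.  r-squared is computed on unphased dosages (composite
LD), the standard panel-free surrogate for haplotype r-squared.

Coordinates are 1-based inclusive internally and converted to/from BED
(0-based half-open) at I/O.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_qc import MISSING, GenotypeMatrix, VariantRecord

__all__ = [
    "Region",
    "GeneModel",
    "genotype_r2",
    "block_borders",
    "genes_in_region",
    "variants_in_gene",
    "read_bed_regions",
    "write_bed_regions",
    "read_bed_genes",
    "write_bed_genes",
]


@dataclass(frozen=True)
class Region:
    """A chromosome interval (1-based inclusive) around a lead variant."""

    chrom: str
    start: int
    end: int
    lead_id: str
    lead_pos: int

    def __post_init__(self) -> None:
        if not (self.start <= self.lead_pos <= self.end):
            raise ValueError("lead position must lie inside the region")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in BED convention (0-based half-open)."""

    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    name: str


def genotype_r2(matrix: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing samples."""
    di = matrix.dosage[:, i]
    dj = matrix.dosage[:, j]
    both = (di != MISSING) & (dj != MISSING)
    x = di[both].astype(float)
    y = dj[both].astype(float)
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError(f"undefined r²: monomorphic variant in pair ({i}, {j})")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def block_borders(
    matrix: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    lead: int,
    r2_min: float = 0.2,
) -> Region:
    """Delineate the LD block around variant index ``lead``.

    ``variants`` must be position-ordered and aligned with the matrix
    columns.  The scan moves outward from the lead in each direction and
    retains the maximal contiguous run of variants with r²(lead, .)
    strictly above ``r2_min``; a neighbour at or below the threshold (or with
    undefined r², e.g. monomorphic) terminates that direction.  A lead
    with no qualifying neighbour yields a single-position region.
    """
    lead_var = variants[lead]
    dlead = matrix.dosage[:, lead]
    known = dlead != MISSING
    if known.sum() < 2 or np.all(dlead[known] == dlead[known][0]):
        raise ValueError("lead variant is monomorphic; block undefined")

    def _above(j: int) -> bool:
        if variants[j].chrom != lead_var.chrom:
            return False
        try:
            return genotype_r2(matrix, lead, j) > r2_min
        except ValueError:
            return False

    left = lead
    while left - 1 >= 0 and _above(left - 1):
        left -= 1
    right = lead
    while right + 1 < len(variants) and _above(right + 1):
        right += 1
    return Region(
        chrom=lead_var.chrom,
        start=variants[left].pos,
        end=variants[right].pos,
        lead_id=lead_var.variant_id,
        lead_pos=lead_var.pos,
    )


def genes_in_region(region: Region, gene_models: Sequence[GeneModel]) -> list[GeneModel]:
    """Genes overlapping the region by at least one base.

    The region (1-based inclusive) is converted to half-open
    ``[start - 1, end)`` so that a gene ending exactly at the region start
    abuts without overlapping.
    """
    r_start = region.start - 1
    r_end = region.end
    return [
        g
        for g in gene_models
        if g.chrom == region.chrom and g.start < r_end and g.end > r_start
    ]


def variants_in_gene(
    gene: GeneModel, variants: Sequence[VariantRecord]
) -> list[int]:
    """Indices of variants belonging to a gene.

    A variant with a gene-symbol annotation belongs to the gene whose name
    matches that symbol, regardless of coordinates (annotation wins over
    coordinates on conflict).  Unannotated variants fall back to coordinate
    overlap with the gene interval (1-based inclusive ``[start+1, end]``
    after BED conversion).
    """
    lo, hi = gene.start + 1, gene.end
    out = []
    for idx, v in enumerate(variants):
        if v.gene is not None:
            if v.gene == gene.name:
                out.append(idx)
        elif v.chrom == gene.chrom and lo <= v.pos <= hi:
            out.append(idx)
    return out


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def write_bed_regions(path, regions: Sequence[Region]) -> None:
    """Regions as BED: 0-based half-open, lead-variant ID in column 4."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in regions:
            w.writerow([r.chrom, r.start - 1, r.end, r.lead_id, r.lead_pos])


def read_bed_regions(path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            lead_id = parts[3] if len(parts) > 3 else "."
            lead_pos = int(parts[4]) if len(parts) > 4 else start0 + 1
            regions.append(Region(chrom, start0 + 1, end, lead_id, lead_pos))
    return regions


def write_bed_genes(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for g in genes:
            w.writerow([g.chrom, g.start, g.end, g.name])


def read_bed_genes(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            genes.append(GeneModel(parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return genes
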