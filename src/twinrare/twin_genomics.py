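"""Twin-genome concordance, zygosity verification and cohort construction.

Identity-by-state (IBS) between two unphased genotypes counts, at every site
non-missing in both samples (including reference-matching sites), the number
of shared alleles ``2 - |dosage_a - dosage_b|``.  Monozygotic (MZ) pairs sit
near 100% IBS, dizygotic (DZ) pairs slightly lower, unrelated pairs lower
still; that ordering both verifies recorded zygosity and flags sample swaps.

Relatedness between two samples is estimated with the KING-robust kinship
estimator rescaled to the coefficient-of-relatedness scale (x2), which is
insensitive to population structure.  Cohort construction drops one member of
each MZ pair (and, in unrelated-only mode, of each DZ pair), keeping the
MDD-diagnosed member by preference, and verifies that no retained pair has a
coefficient of relatedness at or above the configured ceiling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .variant_qc import MISSING, GenotypeMatrix, VariantRecord, is_nonsilent

__all__ = [
    "SampleRecord",
    "PairConcordance",
    "pairwise_ibs",
    "verify_zygosity",
    "calibrate_zygosity_thresholds",
    "mz_discordant_homozygotes",
    "relatedness_coefficient",
    "select_analysis_cohort",
    "write_concordance_tsv",
    "write_cohort_membership_tsv",
]

SEVERITY_ORDER = {"missing": -1, "none": 0, "mild": 1, "moderate": 2, "severe": 3}


@dataclass
class SampleRecord:
    """Identity, twin structure, ancestry, and the four depression variables.

    ``dx`` is the lifetime MDD diagnosis: 0 (never depressed), 1 (diagnosed),
    "bereavement" (bereavement-related episode, excluded from case
    definitions) or "missing".  Severity is recorded only for diagnosed
    individuals; symptom count ranges over 0-9; onset age is the age at the
    first depressive episode.
    """

    sample_id: str
    pair_id: Optional[str]
    zygosity: str  # MZ | DZ | SINGLETON
    ancestry: str
    dx: object = "missing"  # 0 | 1 | "bereavement" | "missing"
    severity: str = "missing"  # none | mild | moderate | severe | missing
    symptom_count: Optional[int] = None
    onset_age: Optional[int] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ", "SINGLETON"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if (self.pair_id is None) != (self.zygosity == "SINGLETON"):
            raise ValueError("pair_id must be absent exactly for singletons")
        if self.severity in ("mild", "moderate", "severe") and self.dx != 1:
            raise ValueError("severity recorded for an undiagnosed sample")

    @property
    def diagnosed(self) -> bool:
        return self.dx == 1


@dataclass(frozen=True)
class PairConcordance:
    sample_a: str
    sample_b: str
    co_genotyped_sites: int
    shared_alleles: int
    total_alleles: int
    ibs_percent: float

    def __post_init__(self) -> None:
        if not (0 <= self.shared_alleles <= self.total_alleles):
            raise ValueError("shared alleles outside [0, total]")
        if self.total_alleles != 2 * self.co_genotyped_sites:
            raise ValueError("total alleles must be twice the co-genotyped sites")


def pairwise_ibs(matrix: GenotypeMatrix, a: str, b: str) -> PairConcordance:
    """IBS concordance between two samples over co-genotyped sites."""
    if a == b:
        raise ValueError("pairwise IBS requires two distinct samples")
    ia, ib = matrix.sample_index(a), matrix.sample_index(b)
    da, db = matrix.dosage[ia], matrix.dosage[ib]
    both = (da != MISSING) & (db != MISSING)
    n_sites = int(both.sum())
    if n_sites == 0:
        raise ValueError(f"no co-genotyped sites between {a} and {b}")
    shared = int((2 - np.abs(da[both].astype(np.int64) - db[both])).sum())
    total = 2 * n_sites
    return PairConcordance(a, b, n_sites, shared, total, 100.0 * shared / total)


def verify_zygosity(
    pairs: Sequence[tuple[str, str, str]],
    concordances: Sequence[PairConcordance],
    mz_min: float,
    dz_min: float,
) -> list[str]:
    """Classify labelled pairs against IBS thresholds.

    ``pairs`` holds (sample_a, sample_b, label) with label MZ or DZ;
    ``concordances`` the matching IBS results in the same order.  A labelled
    MZ pair is consistent when its IBS is at least ``mz_min``; a labelled DZ
    pair when its IBS lies in [``dz_min``, ``mz_min``); anything else is
    inconsistent.  Thresholds are calibrated from the cohort's own empirical
    IBS distributions (see :func:`calibrate_zygosity_thresholds`), not fixed
    constants.
    """
    if not mz_min > dz_min:
        raise ValueError("mz_min must exceed dz_min")
    out = []
    for (sa, sb, label), conc in zip(pairs, concordances):
        ibs = conc.ibs_percent
        if label == "MZ":
            out.append("consistent-MZ" if ibs >= mz_min else "inconsistent")
        elif label == "DZ":
            out.append("consistent-DZ" if dz_min <= ibs < mz_min else "inconsistent")
        else:
            raise ValueError(f"unknown pair label {label!r}")
    return out


def calibrate_zygosity_thresholds(
    mz_ibs: Sequence[float], dz_ibs: Sequence[float], unrelated_ibs: Sequence[float]
) -> tuple[float, float]:
    """Midpoints between class means of observed IBS distributions."""
    m_mz, m_dz, m_un = (float(np.mean(x)) for x in (mz_ibs, dz_ibs, unrelated_ibs))
    if not m_mz > m_dz > m_un:
        raise ValueError("IBS class means are not ordered MZ > DZ > unrelated")
    return (m_mz + m_dz) / 2.0, (m_dz + m_un) / 2.0


def mz_discordant_homozygotes(
    matrix: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    mz_pairs: Sequence[tuple[str, str]],
    cadd_min: float = 20.0,
) -> tuple[list[tuple[int, tuple[str, str]]], list[tuple[int, tuple[str, str]]]]:
    """Scan MZ pairs for discordant homozygous non-silent variants.

    Reports (variant index, pair) events where one co-twin is homozygous
    (dosage 0 or 2), the other co-twin carries a different non-missing
    genotype, and the variant is non-silent.  The second list restricts to
    variants with CADD >= ``cadd_min``; that list is unique by variant (the
    first occurrence per variant is kept).
    """
    nonsilent_idx = np.array([is_nonsilent(v) for v in variants], dtype=bool)
    events: list[tuple[int, tuple[str, str]]] = []
    for a, b in mz_pairs:
        ia, ib = matrix.sample_index(a), matrix.sample_index(b)
        da, db = matrix.dosage[ia], matrix.dosage[ib]
        both = (da != MISSING) & (db != MISSING)
        hom_any = ((da == 0) | (da == 2) | (db == 0) | (db == 2))
        disc = both & hom_any & (da != db) & nonsilent_idx
        for j in np.nonzero(disc)[0]:
            events.append((int(j), (a, b)))
    seen: set[int] = set()
    high_impact = []
    for j, pair in events:
        cadd = variants[j].cadd
        if cadd is not None and cadd >= cadd_min and j not in seen:
            seen.add(j)
            high_impact.append((j, pair))
    return events, high_impact


def relatedness_coefficient(
    matrix: GenotypeMatrix, a: str, b: str, min_sites: int = 1000
) -> float:
    """Coefficient of relatedness: twice the KING-robust kinship.

    r = 2 * (N_AaAa - 2 * N_AA,aa) / (N_Aa(a) + N_Aa(b)) over co-genotyped
    sites, where N_AaAa counts sites at which both samples are heterozygous,
    N_AA,aa counts opposite-homozygote sites, and N_Aa(.) counts heterozygous
    sites per sample.  The symmetric (summed) denominator makes the estimate
    exactly symmetric in the two samples.  Expected values: ~1 for MZ pairs
    or duplicates, ~0.5 for DZ pairs / full siblings, ~0 for unrelated pairs.
    """
    ia, ib = matrix.sample_index(a), matrix.sample_index(b)
    da, db = matrix.dosage[ia], matrix.dosage[ib]
    both = (da != MISSING) & (db != MISSING)
    da, db = da[both], db[both]
    if both.sum() < min_sites:
        raise ValueError(
            f"only {int(both.sum())} co-genotyped sites between {a} and {b}; "
            f"need >= {min_sites} for a stable estimate"
        )
    n_het_a = int((da == 1).sum())
    n_het_b = int((db == 1).sum())
    n_hethet = int(((da == 1) & (db == 1)).sum())
    n_opp = int((((da == 0) & (db == 2)) | ((da == 2) & (db == 0))).sum())
    denom = n_het_a + n_het_b
    if denom == 0:
        raise ValueError("no heterozygous sites in either sample; estimator undefined")
    return 2.0 * (n_hethet - 2.0 * n_opp) / denom


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

def _keep_priority(s: SampleRecord) -> tuple:
    """Sort key: the member to KEEP sorts first (diagnosed, then severer,
    then lexicographically smaller sample id)."""
    return (
        0 if s.diagnosed else 1,
        -SEVERITY_ORDER.get(s.severity, -1),
        s.sample_id,
    )


def select_analysis_cohort(
    samples: Sequence[SampleRecord],
    relatedness: Optional[dict] = None,
    mode: str = "one-mz-excluded",
    ancestry: str = "EUR",
    relatedness_max: float = 0.1,
) -> list[SampleRecord]:
    """Apply the cohort-construction rules.

    ``one-mz-excluded``: restrict to ``ancestry``, drop one member of every
    MZ pair (keeping the diagnosed member, then the severer, then the
    lexicographically smaller id), keep both DZ members and all singletons.
    ``unrelated-only``: additionally keep only one member per DZ pair (same
    priority) and verify via ``relatedness`` (a dict keyed by frozenset of two
    sample ids) that no retained pair reaches ``relatedness_max``.
    """
    if mode not in ("one-mz-excluded", "unrelated-only"):
        raise ValueError(f"unknown cohort mode {mode!r}")
    pool = [s for s in samples if s.ancestry == ancestry]
    by_pair: dict[str, list[SampleRecord]] = {}
    singles: list[SampleRecord] = []
    for s in pool:
        if s.pair_id is None:
            singles.append(s)
        else:
            by_pair.setdefault(s.pair_id, []).append(s)

    kept: list[SampleRecord] = list(singles)
    for members in by_pair.values():
        zyg = members[0].zygosity
        drop_one = zyg == "MZ" or (mode == "unrelated-only" and zyg == "DZ")
        if len(members) < 2 or not drop_one:
            kept.extend(members)
        else:
            kept.append(min(members, key=_keep_priority))

    if mode == "unrelated-only":
        if relatedness is None:
            raise ValueError("unrelated-only mode requires pairwise relatedness")
        offenders = []
        ids = [s.sample_id for s in kept]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r = relatedness.get(frozenset((ids[i], ids[j])))
                if r is not None and r >= relatedness_max:
                    offenders.append((ids[i], ids[j], r))
        if offenders:
            raise ValueError(
                "retained pairs at or above the relatedness ceiling: "
                + "; ".join(f"{a}-{b} (r={r:.3f})" for a, b, r in offenders)
            )
    kept.sort(key=lambda s: s.sample_id)
    return kept


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def write_concordance_tsv(
    path, rows: Iterable[tuple[str, PairConcordance]]
) -> None:
    """Pair-concordance table: relationship label plus IBS summary per pair."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_a", "sample_b", "relationship", "co_genotyped_sites", "ibs_percent"])
        for rel, c in rows:
            w.writerow([c.sample_a, c.sample_b, rel, c.co_genotyped_sites, f"{c.ibs_percent:.6f}"])


def write_cohort_membership_tsv(
    path, samples: Sequence[SampleRecord], kept_ids: set[str], ancestry: str
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "included", "reason"])
        for s in samples:
            if s.sample_id in kept_ids:
                w.writerow([s.sample_id, 1, "included"])
            elif s.ancestry != ancestry:
                w.writerow([s.sample_id, 0, "ancestry"])
            else:
                w.writerow([s.sample_id, 0, "twin-pair exclusion"])
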