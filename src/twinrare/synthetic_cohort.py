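"""Synthetic twin-cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes, so the whole pipeline runs with no external data:

* **LD-blocked haplotypes.**  Variants are grouped into blocks.  Within a
  block every variant is a noisy copy of a latent block haplotype tag: a
  variant copies the tag with probability ``m`` and otherwise draws an
  independent allele at the same frequency, which gives every within-block
  variant pair an expected allelic r-squared of exactly ``m**4`` (the block's
  configured target) while leaving between-block correlation at zero.
* **Two-ancestry stratification.**  Subpopulation allele frequencies diverge
  around the baseline frequency by a Balding-Nichols beta model with
  divergence parameter ``fst_divergence``.
* **Twin structure.**  MZ co-twins share both haplotypes (subject to a rare
  somatic perturbation that shifts one allele of one co-twin); DZ co-twins
  draw from four parental haplotypes with per-block transmission, sharing
  0/1/2 parental copies per block with probabilities 1/4, 1/2, 1/4, so IBD
  segments are contiguous; singletons draw independent haplotypes.
* **Liability-threshold phenotypes.**  A standard-normal liability (genetic
  term + shared-twin term + unique noise) is thresholded into a lifetime
  diagnosis; severity, symptom count and onset age are assigned among the
  diagnosed in liability order so they are mutually correlated and hit the
  configured marginal prevalences.  The genetic coefficient at the planted
  causal variant is calibrated numerically so the population case/control
  allelic odds ratio equals ``exp(causal_log_odds)``.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .region_mapper import GeneModel, Region
from .twin_genomics import SampleRecord
from .variant_qc import MISSING, GenotypeMatrix, VariantRecord

__all__ = [
    "MafSpectrum",
    "PrevalenceTargets",
    "SimulationConfig",
    "SyntheticCohort",
    "CohortTruth",
    "simulate_haplotypes",
    "simulate_cohort",
    "simulate_phenotypes",
    "write_cohort",
    "read_cohort",
]

ANCESTRY_LABELS = ("EUR", "AFR")
FUNC_CLASSES = (
    "nonsynonymous", "frameshift", "stopgain", "stoploss",
    "synonymous", "intronic", "intergenic", "other",
)
FUNC_CLASS_PROBS = (0.18, 0.02, 0.01, 0.005, 0.145, 0.35, 0.20, 0.09)
BASES = ("A", "C", "G", "T")

# Genotype-quality / per-sample-filter noise model: most entries are clean;
# a small fraction of sites are systematically bad so the site filters have
# something to remove.
GQ_MEAN_GOOD = 60.0
GQ_SD = 12.0
LOW_GQ_RATE_GOOD = 0.02
FT_FAIL_RATE_GOOD = 0.01
BAD_SITE_FRACTION = 0.03
LOW_GQ_RATE_BAD = 0.3
FT_FAIL_RATE_BAD = 0.3
VARIANT_SPACING = 500  # bp between adjacent simulated variants


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class MafSpectrum:
    """Baseline allele-frequency distribution: ``low + (high - low) * Beta(a, b)``.

    The default is rare-skewed (most variants below a few percent) with a
    tail of common variants, which gives the QC and association filters a
    realistic mixture to act on.
    """

    low: float = 0.002
    high: float = 0.5
    beta_a: float = 0.25
    beta_b: float = 1.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.low + (self.high - self.low) * rng.beta(self.beta_a, self.beta_b, size)


@dataclass(frozen=True)
class PrevalenceTargets:
    """Marginal phenotype frequencies (fractions of the whole cohort).

    Defaults reproduce the composition of the study cohort: ~10.8% lifetime
    MDD diagnosis, severity split mild/moderate/severe of roughly
    2.7/3.3/3.4% with ~1.8% of the cohort diagnosed but missing severity,
    ~2.3% reporting all nine symptoms, ~4.8% with early (age <= 30) onset,
    and ~0.8% bereavement-related episodes among the non-depressed.
    """

    diagnosis: float = 0.108
    mild: float = 0.027
    moderate: float = 0.033
    severe: float = 0.034
    symptoms9: float = 0.023
    early_onset: float = 0.048
    bereavement: float = 0.008

    def validate(self) -> None:
        for name in ("diagnosis", "mild", "moderate", "severe", "symptoms9",
                     "early_onset", "bereavement"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"prevalence_targets.{name} outside [0, 1]")
        if self.mild + self.moderate + self.severe > self.diagnosis + 1e-9:
            raise ConfigurationError(
                "severity fractions exceed the diagnosis prevalence"
            )


@dataclass(frozen=True)
class SimulationConfig:
    n_mz_pairs: int = 120
    n_dz_pairs: int = 80
    n_singletons: int = 20
    n_variants: int = 300
    n_blocks: int = 10
    block_r2_profile: Optional[Sequence[float]] = None  # default 0.6 per block
    ancestry_fractions: Sequence[float] = (0.92, 0.08)
    fst_divergence: float = 0.05
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    somatic_discordance_rate: float = 1e-4
    causal_variant_index: Optional[int] = None
    causal_log_odds: float = 0.0
    causal_af: Optional[float] = None  # marginal AF of the causal variant
    prevalence_targets: PrevalenceTargets = field(default_factory=PrevalenceTargets)
    missing_genotype_rate: float = 0.002
    seed: int = 0

    @property
    def n_pairs_total(self) -> int:
        return self.n_mz_pairs + self.n_dz_pairs

    @property
    def n_samples(self) -> int:
        return 2 * self.n_pairs_total + self.n_singletons

    def r2_profile(self) -> np.ndarray:
        prof = self.block_r2_profile
        if prof is None:
            prof = [0.6] * self.n_blocks
        prof = np.asarray(prof, dtype=float)
        if prof.size != self.n_blocks:
            raise ConfigurationError(
                "block_r2_profile length must equal n_blocks"
            )
        if ((prof < 0) | (prof > 1)).any():
            raise ConfigurationError("block_r2_profile values outside [0, 1]")
        return prof

    def validate(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_singletons", "n_variants", "n_blocks"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if self.n_variants < self.n_blocks:
            raise ConfigurationError("n_variants must be >= n_blocks")
        if self.n_samples == 0:
            raise ConfigurationError("cohort is empty: no pairs or singletons")
        fr = np.asarray(self.ancestry_fractions, dtype=float)
        if fr.size != len(ANCESTRY_LABELS):
            raise ConfigurationError("ancestry_fractions must cover 2 subpopulations")
        if abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
            raise ConfigurationError("ancestry_fractions must be non-negative and sum to 1")
        if not (0.0 <= self.fst_divergence <= 0.5):
            raise ConfigurationError("fst_divergence outside [0, 0.5]")
        if not (0.0 <= self.somatic_discordance_rate <= 1.0):
            raise ConfigurationError("somatic_discordance_rate outside [0, 1]")
        if not (0.0 <= self.missing_genotype_rate < 1.0):
            raise ConfigurationError("missing_genotype_rate outside [0, 1)")
        if self.causal_variant_index is not None and not (
            0 <= self.causal_variant_index < self.n_variants
        ):
            raise ConfigurationError("causal_variant_index out of range")
        if self.causal_af is not None:
            if self.causal_variant_index is None:
                raise ConfigurationError("causal_af requires causal_variant_index")
            if not (0.0 < self.causal_af < 1.0):
                raise ConfigurationError("causal_af outside (0, 1)")
        self.r2_profile()
        self.prevalence_targets.validate()


@dataclass
class CohortTruth:
    """Planted ground truth of one simulated cohort."""

    causal_variant_index: Optional[int]
    causal_gene: Optional[str]
    causal_beta: float  # liability-scale coefficient after calibration
    target_allelic_or: float
    block_bounds: list  # [(first variant index, last variant index)] per block
    zygosity_by_pair: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    samples: list
    variants: list
    regions: list
    gene_models: list
    truth: CohortTruth


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

def _block_sizes(n_variants: int, n_blocks: int) -> list[int]:
    base = n_variants // n_blocks
    sizes = [base] * n_blocks
    for i in range(n_variants - base * n_blocks):
        sizes[i] += 1
    return sizes


@dataclass
class _BlockModel:
    """Per-block generating parameters shared by all haplotype draws."""

    sizes: list
    bounds: list  # (start, end) variant index per block, end inclusive
    copy_prob: np.ndarray  # m per block, with r2_target = m**4
    freq: np.ndarray  # (n_blocks, n_subpops) block allele frequency
    # (variant index, AF): that variant is drawn independently at the given
    # frequency in every subpopulation, decoupled from its block's LD and
    # divergence, so a planted causal variant has a controlled marginal AF.
    causal_override: Optional[tuple] = None


def _build_block_model(config: SimulationConfig, rng: np.random.Generator) -> _BlockModel:
    sizes = _block_sizes(config.n_variants, config.n_blocks)
    bounds, start = [], 0
    for s in sizes:
        bounds.append((start, start + s - 1))
        start += s
    copy_prob = config.r2_profile() ** 0.25
    base = config.maf_spectrum.draw(rng, config.n_blocks)
    F = config.fst_divergence
    freq = np.empty((config.n_blocks, len(ANCESTRY_LABELS)))
    for k in range(len(ANCESTRY_LABELS)):
        if F == 0:
            freq[:, k] = base
        else:
            a = base * (1.0 - F) / F
            b = (1.0 - base) * (1.0 - F) / F
            freq[:, k] = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)
    override = None
    if config.causal_af is not None:
        override = (config.causal_variant_index, float(config.causal_af))
    return _BlockModel(sizes, bounds, copy_prob, freq, override)


def _draw_block_haplotypes(
    model: _BlockModel, block: int, subpop: int, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """n_hap x block_size binary alleles with within-block r2 = copy_prob**4."""
    size = model.sizes[block]
    p = model.freq[block, subpop]
    m = model.copy_prob[block]
    tag = rng.random(n_hap) < p
    copied = rng.random((n_hap, size)) < m
    independent = rng.random((n_hap, size)) < p
    out = np.where(copied, tag[:, None], independent).astype(np.uint8)
    if model.causal_override is not None:
        start, end = model.bounds[block]
        idx, af = model.causal_override
        if start <= idx <= end:
            out[:, idx - start] = (rng.random(n_hap) < af).astype(np.uint8)
    return out


def _draw_haplotypes(
    model: _BlockModel, subpop: int, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    cols = [
        _draw_block_haplotypes(model, b, subpop, n_hap, rng)
        for b in range(len(model.sizes))
    ]
    return np.concatenate(cols, axis=1)


def simulate_haplotypes(config: SimulationConfig) -> np.ndarray:
    """Phased haplotype pool with block-structured allelic correlation.

    Returns ``2 * (2 * n_pairs_total + n_singletons)`` haplotypes (rows) over
    ``n_variants`` columns, drawn per subpopulation according to
    ``ancestry_fractions``.  Within a block, the expected pairwise allelic
    r-squared equals that block's configured target; between blocks it is 0.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    model = _build_block_model(config, rng)
    n_hap = 2 * config.n_samples
    counts = np.floor(np.asarray(config.ancestry_fractions) * n_hap).astype(int)
    counts[0] += n_hap - counts.sum()
    pools = [
        _draw_haplotypes(model, k, int(c), rng)
        for k, c in enumerate(counts)
        if c > 0
    ]
    return np.concatenate(pools, axis=0)


# ---------------------------------------------------------------------------
# Cohort genotypes
# ---------------------------------------------------------------------------

def _simulate_genotypes(
    config: SimulationConfig, model: _BlockModel, rng: np.random.Generator
) -> tuple[np.ndarray, list[SampleRecord]]:
    """Dosage matrix plus skeleton sample records (phenotypes unfilled)."""
    n_v = config.n_variants
    records: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    fractions = np.asarray(config.ancestry_fractions, dtype=float)

    def draw_ancestry() -> int:
        return int(rng.choice(len(ANCESTRY_LABELS), p=fractions))

    pair_no = 0
    for _ in range(config.n_mz_pairs):
        pair_no += 1
        anc = draw_ancestry()
        h = _draw_haplotypes(model, anc, 2, rng)
        geno = h.sum(axis=0).astype(np.int16)
        g_a, g_b = geno.copy(), geno.copy()
        # Somatic perturbation: one allele in one randomly chosen co-twin.
        hit = rng.random(n_v) < config.somatic_discordance_rate
        for j in np.nonzero(hit)[0]:
            target = g_a if rng.random() < 0.5 else g_b
            if target[j] == 0:
                target[j] = 1
            elif target[j] == 2:
                target[j] = 1
            else:
                target[j] = 0 if rng.random() < 0.5 else 2
        pid = f"MZ{pair_no:04d}"
        for suffix, g in (("a", g_a), ("b", g_b)):
            records.append(
                SampleRecord(f"{pid}{suffix}", pid, "MZ", ANCESTRY_LABELS[anc])
            )
            rows.append(g)

    for _ in range(config.n_dz_pairs):
        pair_no += 1
        anc = draw_ancestry()
        parental = _draw_haplotypes(model, anc, 4, rng)  # m1 m2 f1 f2
        g_a = np.zeros(n_v, dtype=np.int16)
        g_b = np.zeros(n_v, dtype=np.int16)
        for b, (lo, hi) in enumerate(model.bounds):
            sl = slice(lo, hi + 1)
            # Each twin inherits one haplotype per parent, independently per
            # block: 0/1/2 shared parental copies w.p. 1/4, 1/2, 1/4.
            ma, mb = rng.integers(0, 2, 2)
            fa, fb = rng.integers(0, 2, 2)
            g_a[sl] = parental[ma, sl].astype(np.int16) + parental[2 + fa, sl]
            g_b[sl] = parental[mb, sl].astype(np.int16) + parental[2 + fb, sl]
        pid = f"DZ{pair_no:04d}"
        records.append(SampleRecord(f"{pid}a", pid, "DZ", ANCESTRY_LABELS[anc]))
        rows.append(g_a)
        records.append(SampleRecord(f"{pid}b", pid, "DZ", ANCESTRY_LABELS[anc]))
        rows.append(g_b)

    for i in range(config.n_singletons):
        anc = draw_ancestry()
        h = _draw_haplotypes(model, anc, 2, rng)
        records.append(
            SampleRecord(f"SG{i + 1:04d}", None, "SINGLETON", ANCESTRY_LABELS[anc])
        )
        rows.append(h.sum(axis=0).astype(np.int16))

    return np.stack(rows, axis=0), records


def _simulate_quality_layers(
    dosage: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_s, n_v = dosage.shape
    bad_site = rng.random(n_v) < BAD_SITE_FRACTION
    low_gq_rate = np.where(bad_site, LOW_GQ_RATE_BAD, LOW_GQ_RATE_GOOD)
    ft_fail_rate = np.where(bad_site, FT_FAIL_RATE_BAD, FT_FAIL_RATE_GOOD)

    gq = np.maximum(rng.normal(GQ_MEAN_GOOD, GQ_SD, (n_s, n_v)), 0).astype(np.int32)
    low = rng.random((n_s, n_v)) < low_gq_rate[None, :]
    gq = np.where(low, rng.integers(0, 20, (n_s, n_v)), np.maximum(gq, 20))
    ft = rng.random((n_s, n_v)) >= ft_fail_rate[None, :]

    dose = dosage.copy()
    missing = rng.random((n_s, n_v)) < config.missing_genotype_rate
    dose[missing] = MISSING
    gq = np.where(missing, MISSING, gq)
    return dose, gq, ft


def _annotate_variants(
    config: SimulationConfig, model: _BlockModel, rng: np.random.Generator
) -> tuple[list[VariantRecord], list[Region], list[GeneModel]]:
    n_v = config.n_variants
    positions = (np.arange(n_v) + 1) * VARIANT_SPACING
    refs = rng.integers(0, 4, n_v)
    alts = (refs + rng.integers(1, 4, n_v)) % 4
    classes = rng.choice(len(FUNC_CLASSES), size=n_v, p=FUNC_CLASS_PROBS)
    if config.causal_variant_index is not None:
        classes[config.causal_variant_index] = 0  # nonsynonymous
    cadd = np.round(np.clip(rng.exponential(8.0, n_v), 0, 50), 1)

    gene_models: list[GeneModel] = []
    gene_of_variant = np.empty(n_v, dtype=object)
    regions: list[Region] = []
    variant_ids = [f"var{j:06d}" for j in range(n_v)]
    for b, (lo, hi) in enumerate(model.bounds):
        size = hi - lo + 1
        n_genes = 1 if size < 6 else int(rng.integers(1, 4))
        cuts = np.linspace(lo, hi + 1, n_genes + 1).astype(int)
        for g in range(n_genes):
            g_lo, g_hi = cuts[g], cuts[g + 1] - 1
            if g_hi < g_lo:
                continue
            name = f"GENE{b:02d}{chr(ord('A') + g)}"
            gene_models.append(
                GeneModel(
                    chrom="1",
                    start=int(positions[g_lo] - 1 - VARIANT_SPACING // 4),
                    end=int(positions[g_hi] + VARIANT_SPACING // 4),
                    name=name,
                )
            )
            gene_of_variant[g_lo : g_hi + 1] = name
        lead = (lo + hi) // 2
        regions.append(
            Region(
                chrom="1",
                start=int(positions[lo]),
                end=int(positions[hi]),
                lead_id=variant_ids[lead],
                lead_pos=int(positions[lead]),
            )
        )

    block_of_variant = np.empty(n_v, dtype=int)
    for b, (lo, hi) in enumerate(model.bounds):
        block_of_variant[lo : hi + 1] = b
    variants = []
    for j in range(n_v):
        p = float(model.freq[block_of_variant[j], 0])
        variants.append(
            VariantRecord(
                chrom="1",
                pos=int(positions[j]),
                ref=BASES[refs[j]],
                alt=BASES[alts[j]],
                variant_id=variant_ids[j],
                gene=str(gene_of_variant[j]),
                func_class=FUNC_CLASSES[classes[j]],
                cadd=float(cadd[j]),
                ref_pop_af={"gnomad": round(min(1.0, max(0.0, p)), 6)},
            )
        )
    return variants, regions, gene_models


# ---------------------------------------------------------------------------
# Phenotypes (liability-threshold model)
# ---------------------------------------------------------------------------

SHARED_VAR = 0.4  # ACE-style: shared-liability variance (corr 1 MZ, 0.5 DZ)
UNIQUE_VAR = 0.6


def _calibrate_liability(
    p_allele: float, target_or: float, prevalence: float
) -> tuple[float, float]:
    """Solve (beta, threshold) so the liability model yields the target
    marginal prevalence and case/control allelic odds ratio.

    Dosage x ~ Binomial(2, p) under HWE; liability = beta * x + N(0, 1); the
    threshold t fixes the prevalence and beta the allelic odds ratio.
    """
    x = np.array([0.0, 1.0, 2.0])
    px = stats.binom.pmf(x, 2, p_allele)

    def prevalence_given(beta: float, t: float) -> float:
        return float((px * stats.norm.sf(t - beta * x)).sum())

    def allelic_or(beta: float, t: float) -> float:
        case_px = px * stats.norm.sf(t - beta * x)
        ctrl_px = px * stats.norm.cdf(t - beta * x)
        af_case = float((x * case_px).sum() / (2.0 * case_px.sum()))
        af_ctrl = float((x * ctrl_px).sum() / (2.0 * ctrl_px.sum()))
        return (af_case / (1 - af_case)) / (af_ctrl / (1 - af_ctrl))

    t = float(stats.norm.isf(prevalence))
    if target_or == 1.0:
        return 0.0, t
    beta = 0.0
    for _ in range(40):
        beta_new = optimize.brentq(
            lambda b: allelic_or(b, t) - target_or, -8.0, 8.0, xtol=1e-10
        )
        t_new = optimize.brentq(
            lambda tt: prevalence_given(beta_new, tt) - prevalence, -10.0, 10.0,
            xtol=1e-12,
        )
        if abs(beta_new - beta) < 1e-10 and abs(t_new - t) < 1e-12:
            beta, t = beta_new, t_new
            break
        beta, t = beta_new, t_new
    return float(beta), float(t)


def simulate_phenotypes(
    cohort: SyntheticCohort, config: SimulationConfig
) -> list[SampleRecord]:
    """Fill the four depression variables on the cohort's sample records.

    Liability = beta * causal dosage + shared-twin term + unique noise, with
    the shared term correlated 1 within MZ pairs and 0.5 within DZ pairs.
    The lifetime diagnosis thresholds the liability at the configured
    prevalence; severity, symptom count and onset age are assigned among the
    diagnosed in descending-liability order at the configured marginal
    frequencies, so all four variables are mutually correlated.
    """
    config.validate()
    targets = config.prevalence_targets
    samples = cohort.samples
    n = len(samples)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    if config.causal_variant_index is not None:
        j = config.causal_variant_index
        if j >= cohort.genotypes.n_variants:
            raise ConfigurationError("causal_variant_index out of range for cohort")
        dose = cohort.genotypes.dosage[:, j].astype(float)
        dose[dose == MISSING] = 0.0
        p_allele = float(dose.mean() / 2.0) or 1e-4
        beta, t = _calibrate_liability(
            p_allele, float(np.exp(config.causal_log_odds)), targets.diagnosis
        )
        genetic = beta * dose
    else:
        beta = 0.0
        t = float(stats.norm.isf(targets.diagnosis))
        genetic = np.zeros(n)

    shared = np.empty(n)
    sd_s = np.sqrt(SHARED_VAR)
    by_pair: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        if s.pair_id is None:
            shared[i] = rng.normal(0.0, sd_s)
        else:
            by_pair.setdefault(s.pair_id, []).append(i)
    for pid, idx in by_pair.items():
        zyg = samples[idx[0]].zygosity
        common = rng.normal(0.0, sd_s)
        if zyg == "MZ":
            for i in idx:
                shared[i] = common
        else:  # DZ: correlation 0.5
            for i in idx:
                shared[i] = common * np.sqrt(0.5) + rng.normal(0.0, sd_s) * np.sqrt(0.5)

    unique = rng.normal(0.0, np.sqrt(UNIQUE_VAR), n)
    liability = genetic + shared + unique
    dx = liability > t

    diagnosed = np.nonzero(dx)[0]
    order = diagnosed[np.argsort(-liability[diagnosed], kind="stable")]
    n_sev = min(round(targets.severe * n), order.size)
    n_mod = min(round(targets.moderate * n), order.size - n_sev)
    n_mild = min(round(targets.mild * n), order.size - n_sev - n_mod)
    severity = {}
    for rank, i in enumerate(order):
        if rank < n_sev:
            severity[i] = "severe"
        elif rank < n_sev + n_mod:
            severity[i] = "moderate"
        elif rank < n_sev + n_mod + n_mild:
            severity[i] = "mild"
        else:
            severity[i] = "missing"  # diagnosed, severity not recorded

    n_nine = min(round(targets.symptoms9 * n), order.size)
    nine = set(order[:n_nine].tolist())
    n_early = min(round(targets.early_onset * n), order.size)
    early = set(order[:n_early].tolist())

    bereaved = set(
        i for i in np.nonzero(~dx)[0] if rng.random() < targets.bereavement
    )

    out: list[SampleRecord] = []
    for i, s in enumerate(samples):
        if dx[i]:
            sev = severity[i]
            if i in nine:
                symptoms = 9
            else:
                base = {"severe": 7, "moderate": 6, "mild": 5, "missing": 5}[sev]
                symptoms = int(min(8, base + rng.integers(0, 2)))
            onset = (
                int(rng.integers(18, 31)) if i in early else int(rng.integers(31, 61))
            )
            rec = SampleRecord(
                s.sample_id, s.pair_id, s.zygosity, s.ancestry,
                dx=1, severity=sev, symptom_count=symptoms, onset_age=onset,
            )
        elif i in bereaved:
            rec = SampleRecord(
                s.sample_id, s.pair_id, s.zygosity, s.ancestry,
                dx="bereavement", severity="none",
                symptom_count=int(min(4, rng.poisson(1.0))), onset_age=None,
            )
        else:
            rec = SampleRecord(
                s.sample_id, s.pair_id, s.zygosity, s.ancestry,
                dx=0, severity="none",
                symptom_count=int(min(4, rng.poisson(0.4))), onset_age=None,
            )
        out.append(rec)
    cohort.truth.causal_beta = beta
    return out


# ---------------------------------------------------------------------------
# Top-level generator
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic twin cohort, deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    model = _build_block_model(config, rng)
    dosage, samples = _simulate_genotypes(config, model, rng)
    dose, gq, ft = _simulate_quality_layers(dosage, config, rng)
    variants, regions, gene_models = _annotate_variants(config, model, rng)
    matrix = GenotypeMatrix(
        dosage=dose,
        gq=gq,
        sample_pass=ft,
        samples=[s.sample_id for s in samples],
        variant_ids=[v.variant_id for v in variants],
    )
    causal_gene = (
        variants[config.causal_variant_index].gene
        if config.causal_variant_index is not None
        else None
    )
    truth = CohortTruth(
        causal_variant_index=config.causal_variant_index,
        causal_gene=causal_gene,
        causal_beta=0.0,
        target_allelic_or=float(np.exp(config.causal_log_odds)),
        block_bounds=[list(b) for b in model.bounds],
        zygosity_by_pair={
            s.pair_id: s.zygosity for s in samples if s.pair_id is not None
        },
    )
    cohort = SyntheticCohort(matrix, samples, variants, regions, gene_models, truth)
    cohort.samples = simulate_phenotypes(cohort, config)
    return cohort


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=twinrare-synthetic-cohort
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=q10,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-sample filter status">
##contig=<ID=1>
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort(cohort: SyntheticCohort, output_dir) -> dict:
    """Serialize a cohort to VCF + TSV + BED files; returns the path map."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "annotations": out / "annotations.tsv",
        "regions": out / "regions.bed",
        "gene_models": out / "gene_models.bed",
        "truth": out / "truth.json",
    }
    m = cohort.genotypes
    with open(paths["vcf"], "w", newline="") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        for j, v in enumerate(cohort.variants):
            cols = [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", "PASS", ".", "GT:GQ:FT"]
            for i in range(m.n_samples):
                gt = _GT_CODE[int(m.dosage[i, j])]
                gq = "." if m.gq[i, j] == MISSING else str(int(m.gq[i, j]))
                ft = "PASS" if m.sample_pass[i, j] else "q10"
                cols.append(f"{gt}:{gq}:{ft}")
            fh.write("\t".join(cols) + "\n")

    with open(paths["phenotypes"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sample_id", "pair_id", "zygosity", "ancestry", "dx", "severity",
             "symptom_count", "onset_age"]
        )
        for s in cohort.samples:
            w.writerow(
                [
                    s.sample_id,
                    s.pair_id if s.pair_id is not None else "NA",
                    s.zygosity,
                    s.ancestry,
                    "NA" if s.dx == "missing" else s.dx,
                    "NA" if s.severity == "missing" else s.severity,
                    "NA" if s.symptom_count is None else s.symptom_count,
                    "NA" if s.onset_age is None else s.onset_age,
                ]
            )

    with open(paths["annotations"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["chrom", "pos", "ref", "alt", "variant_id", "gene", "func_class",
             "cadd", "gnomad_af"]
        )
        for v in cohort.variants:
            w.writerow(
                [v.chrom, v.pos, v.ref, v.alt, v.variant_id, v.gene or "NA",
                 v.func_class, "NA" if v.cadd is None else v.cadd,
                 v.ref_pop_af.get("gnomad", "NA")]
            )

    from .region_mapper import write_bed_genes, write_bed_regions

    write_bed_regions(paths["regions"], cohort.regions)
    write_bed_genes(paths["gene_models"], cohort.gene_models)
    with open(paths["truth"], "w") as fh:
        fh.write(cohort.truth.to_json() + "\n")
    return paths


def read_phenotypes_tsv(path) -> list[SampleRecord]:
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            dx_raw = row["dx"]
            dx: object
            if dx_raw == "NA":
                dx = "missing"
            elif dx_raw in ("0", "1"):
                dx = int(dx_raw)
            else:
                dx = dx_raw
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    pair_id=None if row["pair_id"] == "NA" else row["pair_id"],
                    zygosity=row["zygosity"],
                    ancestry=row["ancestry"],
                    dx=dx,
                    severity="missing" if row["severity"] == "NA" else row["severity"],
                    symptom_count=None if row["symptom_count"] == "NA" else int(row["symptom_count"]),
                    onset_age=None if row["onset_age"] == "NA" else int(row["onset_age"]),
                )
            )
    return records


def read_annotations_tsv(path) -> list[VariantRecord]:
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                VariantRecord(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    variant_id=row["variant_id"],
                    gene=None if row["gene"] == "NA" else row["gene"],
                    func_class=row["func_class"],
                    cadd=None if row["cadd"] == "NA" else float(row["cadd"]),
                    ref_pop_af={}
                    if row.get("gnomad_af", "NA") == "NA"
                    else {"gnomad": float(row["gnomad_af"])},
                )
            )
    return records


def read_cohort(input_dir) -> SyntheticCohort:
    """Round-trip reader for :func:`write_cohort` output."""
    from .region_mapper import read_bed_genes, read_bed_regions
    from .variant_qc import read_vcf

    d = Path(input_dir)
    matrix, _ = read_vcf(d / "genotypes.vcf")
    samples = read_phenotypes_tsv(d / "phenotypes.tsv")
    variants = read_annotations_tsv(d / "annotations.tsv")
    regions = read_bed_regions(d / "regions.bed")
    gene_models = read_bed_genes(d / "gene_models.bed")
    with open(d / "truth.json") as fh:
        t = json.load(fh)
    truth = CohortTruth(
        causal_variant_index=t["causal_variant_index"],
        causal_gene=t["causal_gene"],
        causal_beta=t["causal_beta"],
        target_allelic_or=t["target_allelic_or"],
        block_bounds=t["block_bounds"],
        zygosity_by_pair=t["zygosity_by_pair"],
    )
    matrix.variant_ids = [v.variant_id for v in variants]
    return SyntheticCohort(matrix, samples, variants, regions, gene_models, truth)
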