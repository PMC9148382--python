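"""Shared fixtures and small builders for the test suite."""

import logging

import numpy as np
import pytest

from twinrare.synthetic_cohort import SimulationConfig, simulate_cohort
from twinrare.variant_qc import MISSING, GenotypeMatrix, VariantRecord

logging.getLogger("twinrare").setLevel(logging.ERROR)


def build_matrix(dosage, gq=None, sample_pass=None, samples=None, variant_ids=None):
    """GenotypeMatrix from a dosage array with permissive defaults."""
    dosage = np.asarray(dosage, dtype=np.int16)
    if gq is None:
        gq = np.where(dosage == MISSING, MISSING, 99)
    if sample_pass is None:
        sample_pass = np.ones_like(dosage, dtype=bool)
    if samples is None:
        samples = [f"S{i:03d}" for i in range(dosage.shape[0])]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(dosage.shape[1])]
    return GenotypeMatrix(
        dosage=dosage,
        gq=np.asarray(gq),
        sample_pass=np.asarray(sample_pass, dtype=bool),
        samples=samples,
        variant_ids=variant_ids,
    )


def variant(pos=100, func_class="nonsynonymous", gene=None, cadd=None,
            chrom="1", vid=None):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        variant_id=vid or f"var{pos}",
        gene=gene,
        func_class=func_class,
        cadd=cadd,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact twin cohort reused by read-only tests."""
    cfg = SimulationConfig(
        n_mz_pairs=25,
        n_dz_pairs=15,
        n_singletons=20,
        n_variants=240,
        n_blocks=8,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_mz_pairs=25,
        n_dz_pairs=15,
        n_singletons=20,
        n_variants=240,
        n_blocks=8,
        seed=11,
    )
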