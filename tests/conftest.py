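"""Shared fixtures: small deterministic cohorts and hand-built genotype data."""

import numpy as np
import pandas as pd
import pytest

from missnp.genio import SAMPLE_COLUMNS, SNP_COLUMNS, GenotypeData
from missnp.syndata import SimConfig, generate_cohort


def make_genotypes(dosages, chrom=None, pos=None, phenotype=None, fid=None,
                   snp_ids=None, a1="A", a2="G"):
    """Build a GenotypeData from a dosage array with sensible defaults."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    snps = pd.DataFrame({
        "chrom": chrom if chrom is not None else [1] * m,
        "snp": snp_ids if snp_ids is not None else [f"rs{j + 1}" for j in range(m)],
        "cm": 0.0,
        "pos": pos if pos is not None else list(range(1000, 1000 + m)),
        "a1": a1,
        "a2": a2,
    })[SNP_COLUMNS]
    samples = pd.DataFrame({
        "fid": fid if fid is not None else [f"F{i}" for i in range(n)],
        "iid": [f"I{i}" for i in range(n)],
        "father": "0",
        "mother": "0",
        "sex": 1,
        "phenotype": phenotype if phenotype is not None else [1] * n,
    })[SAMPLE_COLUMNS]
    return GenotypeData(d, snps, samples)


SMALL_CONFIG = SimConfig(
    n_founder_cases=150, n_founder_controls=150, n_snps=800,
    n_causal_main=10, beta_main=0.5, n_causal_sub=5, beta_sub=0.6,
    subclass_fraction=0.1, fst=0.0, pop2_fraction=0.0, missing_rate=0.002,
    n_monomorphic=5, n_hwe_violating=4, n_high_missing=4, n_no_rsid=3,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with planted failures (session-cached)."""
    return generate_cohort(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def clean_cohort():
    """A small clean cohort: no planted failures, no missingness."""
    cfg = SimConfig(
        n_founder_cases=120, n_founder_controls=120, n_snps=400,
        n_causal_main=8, beta_main=0.5, n_causal_sub=0, beta_sub=0.0,
        subclass_fraction=0.0, fst=0.0, pop2_fraction=0.0, missing_rate=0.0,
        n_monomorphic=0, n_hwe_violating=0, n_high_missing=0, n_no_rsid=0,
    )
    return generate_cohort(cfg, seed=23)
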