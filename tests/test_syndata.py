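"""Synthetic cohort generator: frequency model, genotypes, phenotypes,
families, planted QC failures, manifest invariants, determinism."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import kstest

from missnp.assoc import association_scan
from missnp.model import auc_score
from missnp.syndata import (
    ConfigurationError,
    GenerationError,
    SimConfig,
    _solve_intercept,
    draw_allele_frequencies,
    generate_cohort,
    simulate_genotypes,
)


# ---------------------------------------------------------------------------
# configuration


def test_config_validation_errors():
    with pytest.raises(ConfigurationError, match="fst"):
        SimConfig(fst=0.7).validate()
    with pytest.raises(ConfigurationError, match="maf_range"):
        SimConfig(maf_range=(0.0, 0.5)).validate()
    with pytest.raises(ConfigurationError, match="relatives"):
        SimConfig(relatives_per_case=3).validate()
    with pytest.raises(ConfigurationError, match="exceed"):
        SimConfig(n_snps=50).validate()


# ---------------------------------------------------------------------------
# allele frequencies


def test_fst_zero_keeps_ancestral_frequencies_exactly():
    cfg = SimConfig(fst=0.0, n_snps=500)
    rng = np.random.default_rng(0)
    freqs = draw_allele_frequencies(cfg, rng)
    assert freqs.shape[0] == 2
    np.testing.assert_array_equal(freqs[0], freqs[1])


def test_degenerate_maf_range_gives_half_everywhere():
    cfg = SimConfig(maf_range=(0.5, 0.5), fst=0.0, n_snps=200)
    freqs = draw_allele_frequencies(cfg, np.random.default_rng(1))
    np.testing.assert_allclose(freqs, 0.5)


def test_fst_divergence_is_monotone():
    # Mean |p1 - p2| grows with fst (Beta variance 2 fst p (1-p)).
    gaps = {}
    for fst in (0.005, 0.05):
        diffs = []
        for seed in range(10):
            cfg = SimConfig(fst=fst, n_snps=2000)
            freqs = draw_allele_frequencies(cfg, np.random.default_rng(seed))
            diffs.append(np.abs(freqs[0] - freqs[1]).mean())
        gaps[fst] = np.mean(diffs)
    assert gaps[0.05] > gaps[0.005]


# ---------------------------------------------------------------------------
# genotypes


def test_binomial_moments_at_half():
    cfg = SimConfig(n_founder_cases=5000, n_founder_controls=5000,
                    n_snps=50, maf_range=(0.5, 0.5), fst=0.0, pop2_fraction=0.0,
                    n_causal_main=0, n_causal_sub=0, n_monomorphic=0,
                    n_hwe_violating=0, n_high_missing=0, n_no_rsid=0)
    freqs = draw_allele_frequencies(cfg, np.random.default_rng(2))
    geno, _ = simulate_genotypes(freqs, cfg, np.random.default_rng(3))
    mean = geno.dosages.mean()
    se = np.sqrt(0.5 / (10_000 * 50))  # Var(binomial(2, .5)) = 0.5
    assert abs(mean - 1.0) < 3 * se


def test_generation_is_deterministic():
    cfg = SimConfig(n_founder_cases=60, n_founder_controls=60, n_snps=300,
                    relatives_per_case=1)
    a = generate_cohort(cfg, seed=5)
    b = generate_cohort(cfg, seed=5)
    np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
    assert list(a.genotypes.samples["phenotype"]) == list(b.genotypes.samples["phenotype"])
    assert a.truth.main_causal_snps == b.truth.main_causal_snps
    assert a.truth.subclass_members == b.truth.subclass_members


# ---------------------------------------------------------------------------
# phenotypes


def test_intercept_solver_hits_target():
    rng = np.random.default_rng(4)
    scores = rng.binomial(2, 0.3, size=5000).astype(float)
    alpha = _solve_intercept(0.5, scores, 0.4)
    assert abs(np.mean(expit(alpha + 0.5 * scores)) - 0.4) < 1e-5


def test_unattainable_balance_raises():
    scores = np.full(10, 30.0)
    with pytest.raises(GenerationError, match="unattainable"):
        _solve_intercept(100.0, scores, 0.5)  # share(alpha) ~ 1 for all alpha


def test_null_betas_give_chance_level_labels():
    cfg = SimConfig(n_founder_cases=400, n_founder_controls=400, n_snps=200,
                    beta_main=0.0, beta_sub=0.0, subclass_fraction=0.0,
                    fst=0.0, pop2_fraction=0.0, missing_rate=0.0,
                    n_monomorphic=0, n_hwe_violating=0, n_high_missing=0,
                    n_no_rsid=0)
    bundle = generate_cohort(cfg, seed=6)
    geno = bundle.genotypes
    model = bundle.truth.phenotype_model
    eta = model.linear_predictor(geno.dosages.astype(float),
                                 np.zeros(geno.n_samples, bool))
    y = (geno.samples["phenotype"].to_numpy() == 2).astype(int)
    assert abs(auc_score(y, eta) - 0.5) < 0.08  # constant predictor, tie AUC


def test_subclass_fraction_zero_means_no_subclass():
    cfg = SimConfig(n_founder_cases=50, n_founder_controls=50, n_snps=200,
                    subclass_fraction=0.0)
    bundle = generate_cohort(cfg, seed=7)
    assert bundle.truth.subclass_members == []


def test_main_effect_bayes_auc_exceeds_threshold():
    # The generative linear predictor itself separates cases from controls
    # at AUC > 0.75 on a fresh draw at headline effect sizes.
    cfg = SimConfig(n_founder_cases=1000, n_founder_controls=1000,
                    n_snps=1000, n_causal_main=20, beta_main=0.4,
                    subclass_fraction=0.0, fst=0.0, pop2_fraction=0.0,
                    missing_rate=0.0, n_monomorphic=0, n_hwe_violating=0,
                    n_high_missing=0, n_no_rsid=0)
    bundle = generate_cohort(cfg, seed=8)
    geno, model = bundle.genotypes, bundle.truth.phenotype_model
    eta = model.linear_predictor(geno.dosages.astype(float),
                                 np.zeros(geno.n_samples, bool))
    y = (geno.samples["phenotype"].to_numpy() == 2).astype(int)
    assert auc_score(y, eta) > 0.75


# ---------------------------------------------------------------------------
# families


def test_no_relatives_means_singleton_families():
    ped = generate_cohort(SimConfig(n_founder_cases=30, n_founder_controls=30,
                                    n_snps=300), seed=9).pedigree
    assert (ped.table.groupby("fid").size() == 1).all()


def test_sibling_dosage_correlation_near_half():
    cfg = SimConfig(n_founder_cases=300, n_founder_controls=50, n_snps=3000,
                    relatives_per_case=1, fst=0.0, pop2_fraction=0.0,
                    missing_rate=0.0, n_monomorphic=0, n_hwe_violating=0,
                    n_high_missing=0, n_no_rsid=0, subclass_fraction=0.0)
    bundle = generate_cohort(cfg, seed=10)
    geno = bundle.genotypes
    kin = bundle.truth.kinship_true
    phi = kin.values
    pairs = np.argwhere(np.triu(phi, 1) == 0.25)
    assert len(pairs) >= 200
    # center each SNP column: the per-SNP allele-frequency variation is shared
    # by both siblings and would otherwise inflate the raw correlation
    d = geno.dosages.astype(float)
    dc = d - d.mean(axis=0)
    corrs = []
    for i, j in pairs[:200]:
        corrs.append((dc[i] @ dc[j]) / np.sqrt((dc[i] @ dc[i]) * (dc[j] @ dc[j])))
    # Cov(Xi, Xj) = 4 phi p(1-p) -> correlation 2 phi = 0.5
    assert abs(np.mean(corrs) - 0.5) < 0.03


def test_kinship_true_structure(small_cohort):
    phi = small_cohort.truth.kinship_true.values
    np.testing.assert_allclose(np.diag(phi), 0.5)
    off = phi[~np.eye(len(phi), dtype=bool)]
    assert set(np.unique(off)) <= {0.0, 0.25}


# ---------------------------------------------------------------------------
# planted failures


def test_planted_failure_counts_and_disjointness(small_cohort):
    truth = small_cohort.truth
    pf = truth.planted_failures
    assert len(pf["monomorphic"]) == 5
    assert len(pf["hwe"]) == 4
    assert len(pf["high_missing"]) == 4
    assert len(pf["no_rsid"]) == 3
    sets = [set(v) for v in pf.values()]
    causal = set(truth.main_causal_snps) | set(truth.sub_causal_snps)
    for i, a in enumerate(sets):
        assert not (a & causal)
        for b in sets[i + 1:]:
            assert not (a & b)


def test_planted_monomorphic_have_single_value(small_cohort):
    geno = small_cohort.genotypes
    cols = geno.snp_positions(small_cohort.truth.planted_failures["monomorphic"])
    for c in cols:
        col = geno.dosages[:, c]
        vals = set(col[col != -1].tolist())
        assert len(vals) == 1


def test_full_inbreeding_has_zero_heterozygotes():
    cfg = SimConfig(n_founder_cases=200, n_founder_controls=200, n_snps=300,
                    n_hwe_violating=10, hwe_inbreeding=1.0, fst=0.0,
                    pop2_fraction=0.0, missing_rate=0.0, n_monomorphic=0,
                    n_high_missing=0, n_no_rsid=0)
    bundle = generate_cohort(cfg, seed=12)
    geno = bundle.genotypes
    cols = geno.snp_positions(bundle.truth.planted_failures["hwe"])
    assert not (geno.dosages[:, cols] == 1).any()


def test_background_missingness_rate():
    cfg = SimConfig(n_founder_cases=500, n_founder_controls=500, n_snps=1000,
                    missing_rate=0.01, n_monomorphic=0, n_hwe_violating=0,
                    n_high_missing=0, n_no_rsid=0, fst=0.0, pop2_fraction=0.0)
    geno = generate_cohort(cfg, seed=13).genotypes
    frac = (geno.dosages == -1).mean()
    se = np.sqrt(0.01 * 0.99 / geno.dosages.size)
    assert abs(frac - 0.01) < 3 * se


def test_no_rsid_snps_lack_rs_prefix(small_cohort):
    truth = small_cohort.truth
    assert all(not s.startswith("rs") for s in truth.planted_failures["no_rsid"])


# ---------------------------------------------------------------------------
# exchangeability under the full null


def test_null_cohort_p_values_are_uniform():
    cfg = SimConfig(n_founder_cases=200, n_founder_controls=200, n_snps=5000,
                    beta_main=0.0, beta_sub=0.0, subclass_fraction=0.0,
                    fst=0.0, pop2_fraction=0.0, missing_rate=0.0,
                    n_monomorphic=0, n_hwe_violating=0, n_high_missing=0,
                    n_no_rsid=0)
    rejected = 0
    for seed in range(5):
        geno = generate_cohort(cfg, seed=seed).genotypes
        p = association_scan(geno)["p"].to_numpy()
        if kstest(p, "uniform").pvalue < 0.01:
            rejected += 1
    assert rejected <= 1
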