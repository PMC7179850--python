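"""Association statistics: pedigree kinship, Hardy-Weinberg tests,
kinship-corrected chi-square, and SNP pre-selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from missnp.assoc import (
    KinshipMatrix,
    PedigreeError,
    association_scan,
    corrected_chi2,
    hwe_scan,
    hwe_test,
    kinship_from_pedigree,
    preselect,
)
from missnp.genio import MISSING, Pedigree
from missnp.syndata import SimConfig, generate_cohort

from conftest import make_genotypes


def _ped(rows):
    return Pedigree(pd.DataFrame(rows, columns=["fid", "iid", "father", "mother"]))


# ---------------------------------------------------------------------------
# pedigree kinship


def test_kinship_textbook_values():
    ped = _ped([
        ("F", "gpa", "0", "0"),
        ("F", "gma", "0", "0"),
        ("F", "dad", "gpa", "gma"),
        ("F", "mom", "0", "0"),
        ("F", "kid1", "dad", "mom"),
        ("F", "kid2", "dad", "mom"),
    ])
    kin = kinship_from_pedigree(ped)
    phi = pd.DataFrame(kin.values, index=kin.ids, columns=kin.ids)
    assert phi.loc["kid1", "kid1"] == 0.5          # non-inbred self
    assert phi.loc["kid1", "kid2"] == 0.25         # full siblings
    assert phi.loc["dad", "kid1"] == 0.25          # parent-offspring
    assert phi.loc["gpa", "kid1"] == 0.125         # grandparent
    assert phi.loc["gpa", "gma"] == 0.0            # unrelated founders
    assert phi.loc["mom", "dad"] == 0.0


def test_kinship_inbred_child_of_siblings():
    ped = _ped([
        ("F", "a", "0", "0"),
        ("F", "b", "0", "0"),
        ("F", "s1", "a", "b"),
        ("F", "s2", "a", "b"),
        ("F", "inb", "s1", "s2"),
    ])
    kin = kinship_from_pedigree(ped)
    phi = pd.DataFrame(kin.values, index=kin.ids, columns=kin.ids)
    # phi_ii = 0.5 (1 + phi_parents) = 0.5 (1 + 0.25)
    assert phi.loc["inb", "inb"] == pytest.approx(0.625)


def test_kinship_cycle_rejected():
    ped = _ped([
        ("F", "a", "b", "0"),
        ("F", "b", "a", "0"),
    ])
    with pytest.raises(PedigreeError, match="cycle"):
        kinship_from_pedigree(ped)


def test_kinship_matches_generator_truth(small_cohort):
    # sanity: small_cohort has no relatives -> pedigree kinship is identity
    kin = kinship_from_pedigree(small_cohort.pedigree)
    sub = kin.subset(small_cohort.genotypes.samples["iid"])
    np.testing.assert_array_equal(sub.values,
                                  small_cohort.truth.kinship_true.values)


def test_kinship_sib_cohort_pedigree_agrees_with_truth():
    cfg = SimConfig(n_founder_cases=40, n_founder_controls=40, n_snps=300,
                    relatives_per_case=1)
    bundle = generate_cohort(cfg, seed=3)
    kin = kinship_from_pedigree(bundle.pedigree)
    sub = kin.subset(bundle.genotypes.samples["iid"])
    np.testing.assert_allclose(sub.values, bundle.truth.kinship_true.values)


def test_kinship_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        KinshipMatrix(np.array([[0.5, 0.1], [0.2, 0.5]]), ["a", "b"])
    with pytest.raises(ValueError, match="shape"):
        KinshipMatrix(np.eye(3) / 2, ["a", "b"])
    assert KinshipMatrix.identity(["a", "b"]).is_unrelated


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def test_hwe_perfect_proportions_give_zero():
    stat, p = hwe_test(25, 50, 25)
    assert stat == 0.0 and p == 1.0


def test_hwe_known_chi_square_value():
    # p_hat = 0.5, expected (25, 50, 25) -> chi2 = 25/25 + 100/50 + 25/25 = 4
    stat, p = hwe_test(30, 40, 30)
    assert stat == pytest.approx(4.0)
    assert p == pytest.approx(float(chi2.sf(4.0, 1)))


def test_hwe_monomorphic_convention():
    assert hwe_test(100, 0, 0) == (0.0, 1.0)
    assert hwe_test(0, 0, 57) == (0.0, 1.0)


def test_hwe_input_validation():
    with pytest.raises(ValueError, match="non-negative"):
        hwe_test(-1, 2, 3)
    with pytest.raises(ValueError, match="positive"):
        hwe_test(0, 0, 0)


def test_hwe_exact_agrees_with_chi2_at_scale():
    # at large counts the exact p and the chi-square p agree to ~10%
    _, p_exact = hwe_test(300, 500, 200, exact=True)
    _, p_chi = hwe_test(300, 500, 200)
    assert abs(p_exact - p_chi) < 0.1 * max(p_exact, p_chi) + 1e-3


def test_hwe_scan_matches_scalar_test():
    rng = np.random.default_rng(0)
    d = rng.integers(0, 3, size=(60, 25)).astype(np.int8)
    d[rng.random(d.shape) < 0.05] = MISSING
    data = make_genotypes(d)
    scan_p = hwe_scan(data)
    for j in range(25):
        col = d[:, j]
        col = col[col != MISSING]
        _, p = hwe_test(int((col == 2).sum()), int((col == 1).sum()),
                        int((col == 0).sum()))
        assert scan_p[j] == pytest.approx(p)


# ---------------------------------------------------------------------------
# corrected chi-square


def test_corrected_chi2_toy_value():
    # cases {2,2,1}, controls {0,1,0}: D = 4/3, p_hat = 1/2,
    # var = 2 * 1/4 * (1/3 + 1/3) = 1/3 -> stat = (16/9)/(1/3) = 16/3
    dos = np.array([2, 2, 1, 0, 1, 0], dtype=float)
    is_case = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
    stat, p = corrected_chi2(dos, is_case)
    assert stat == pytest.approx(16.0 / 3.0)
    assert p == pytest.approx(float(chi2.sf(16.0 / 3.0, 1)))


def test_corrected_chi2_duplicates_with_kinship_recover_original():
    # duplicating every subject doubles the naive statistic; declaring the
    # duplicates as kinship-0.5 pairs restores the original value exactly
    dos = np.array([2, 2, 1, 0, 1, 0], dtype=float)
    is_case = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
    dup = np.repeat(dos, 2)
    dup_case = np.repeat(is_case, 2)
    stat_naive, _ = corrected_chi2(dup, dup_case)
    assert stat_naive == pytest.approx(32.0 / 3.0)
    phi = 0.5 * np.eye(12)
    for k in range(0, 12, 2):
        phi[k, k + 1] = phi[k + 1, k] = 0.5
    kin = KinshipMatrix(phi, [f"s{i}" for i in range(12)])
    stat_corr, _ = corrected_chi2(dup, dup_case, kin)
    assert stat_corr == pytest.approx(16.0 / 3.0)


def test_corrected_chi2_monomorphic_and_missing():
    is_case = np.array([1, 1, 0, 0], dtype=bool)
    stat, p = corrected_chi2(np.array([2.0, 2, 2, 2]), is_case)
    assert (stat, p) == (0.0, 1.0)
    # missing entries are excluded pairwise
    stat_m, _ = corrected_chi2(np.array([2.0, MISSING, 0, 0]), is_case)
    stat_r, _ = corrected_chi2(np.array([2.0, 0, 0]),
                               np.array([1, 0, 0], dtype=bool))
    assert stat_m == pytest.approx(stat_r)


def test_corrected_chi2_requires_both_classes():
    with pytest.raises(ValueError, match="cases and controls"):
        corrected_chi2(np.array([1.0, 2.0]), np.array([True, True]))


def test_scan_matches_corrected_chi2_with_kinship_and_missing():
    cfg = SimConfig(n_founder_cases=50, n_founder_controls=50, n_snps=250,
                    relatives_per_case=1, missing_rate=0.01,
                    n_monomorphic=2, n_hwe_violating=2, n_high_missing=2,
                    n_no_rsid=2)
    bundle = generate_cohort(cfg, seed=5)
    geno, kin = bundle.genotypes, bundle.truth.kinship_true
    phen = geno.samples["phenotype"].to_numpy()
    keep = np.isin(phen, (1, 2))
    sub = geno.subset_samples(keep)
    is_case = sub.samples["phenotype"].to_numpy() == 2
    stat_ref, p_ref = corrected_chi2(sub.dosages, is_case,
                                     kin.subset(sub.samples["iid"]))
    table = association_scan(geno, kin)
    np.testing.assert_allclose(table["stat"].to_numpy(), stat_ref, atol=1e-10)
    np.testing.assert_allclose(table["p"].to_numpy(), p_ref, atol=1e-10)


def test_scan_requires_both_classes():
    data = make_genotypes([[0, 1], [1, 2]], phenotype=[2, 2])
    with pytest.raises(ValueError, match="cases and controls"):
        association_scan(data)


def test_type_one_error_calibrated_for_unrelated_samples():
    rng = np.random.default_rng(17)
    n, m = 1000, 20000
    p = rng.uniform(0.05, 0.5, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    is_case = np.zeros(n, dtype=bool)
    is_case[:500] = True
    _, pvals = corrected_chi2(dos, is_case)
    rejection = float((pvals < 0.05).mean())
    assert 0.04 <= rejection <= 0.06


# ---------------------------------------------------------------------------
# pre-selection


def _toy_table():
    return pd.DataFrame({
        "snp": ["a", "b", "c", "d"],
        "chrom": [2, 1, 1, 3],
        "pos": [5, 9, 4, 1],
        "p": [0.5, 0.01, 0.01, 1.0],
        "stat": [1.0, 6.0, 6.0, 0.0],
    })


def test_preselect_orders_by_p_then_genome_position():
    # ties at p=0.01 break by (chrom, pos): c before b
    assert preselect(_toy_table(), "top_k", 3) == ["c", "b", "a"]
    assert preselect(_toy_table(), "p_threshold", 0.05) == ["c", "b"]


def test_preselect_top_k_larger_than_table_warns_and_returns_all():
    with pytest.warns(UserWarning, match="returning all"):
        out = preselect(_toy_table(), "top_k", 10)
    assert out == ["c", "b", "a", "d"]


def test_preselect_threshold_one_selects_every_snp():
    with pytest.warns(UserWarning, match="every SNP"):
        out = preselect(_toy_table(), "p_threshold", 1.0)
    assert out == ["c", "b", "a", "d"]  # includes p == 1.0


def test_preselect_unknown_mode_and_empty_table():
    with pytest.raises(ValueError, match="mode"):
        preselect(_toy_table(), "bogus", 1)
    with pytest.raises(ValueError, match="empty"):
        preselect(_toy_table().iloc[:0], "top_k", 1)


def test_preselect_null_threshold_yield_matches_expectation():
    # 10^4 null SNPs at alpha = 1e-3 -> ~10 selections, +/- 3 sd
    rng = np.random.default_rng(29)
    n, m = 400, 10000
    p = rng.uniform(0.05, 0.5, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    data = make_genotypes(dos, chrom=[1] * m, pos=list(range(1, m + 1)),
                          phenotype=rng.permutation([1] * 200 + [2] * 200))
    table = association_scan(data)
    hits = preselect(table, "p_threshold", 1e-3)
    assert abs(len(hits) - 10) <= 3 * np.sqrt(10)


def test_preselect_top_k_enriches_causal_snps():
    for seed in range(5):
        cfg = SimConfig(n_founder_cases=400, n_founder_controls=400,
                        n_snps=1000, n_causal_main=10, beta_main=0.5,
                        subclass_fraction=0.0, fst=0.0, pop2_fraction=0.0,
                        missing_rate=0.0, n_monomorphic=0, n_hwe_violating=0,
                        n_high_missing=0, n_no_rsid=0)
        bundle = generate_cohort(cfg, seed=seed)
        table = association_scan(bundle.genotypes)
        top = set(preselect(table, "top_k", 100))
        causal = set(bundle.truth.main_causal_snps)
        recovered = len(top & causal) / len(causal)
        assert recovered > 100 / cfg.n_snps
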