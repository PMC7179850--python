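"""Synthetic GWAS cohort generator.

Emulates a familial case-control study: two ancestry clusters under a
Balding-Nichols allele-frequency model, a majority disease signal carried
by one causal SNP set, a hidden sub-class of subjects whose status is
driven by a *different* SNP set, nuclear families (full siblings of
affected founders), and planted quality-control failures (monomorphic
SNPs, Hardy-Weinberg violations, high missingness, missing rs IDs).

Every draw flows from a single integer seed, so a fixed configuration is
reproducible bit for bit.  A :class:`TruthManifest` records the planted
structure for downstream validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .genio import MISSING, SNP_COLUMNS, SAMPLE_COLUMNS, GenotypeData, Pedigree

# approximate autosome lengths (Mb) used to spread SNPs over chromosomes
_CHROM_MB = np.array(
    [249, 243, 199, 191, 181, 171, 159, 146, 141, 136,
     135, 134, 115, 107, 103, 90, 81, 78, 59, 63, 48, 51],
    dtype=float,
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


class GenerationError(RuntimeError):
    """Raised when a configuration cannot be realized (e.g. unattainable balance)."""


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the study conditions the package is exercised under:
    ~2,200 subjects (two ancestry clusters, 10% minority), 20,000 common
    biallelic autosomal SNPs, 20 majority-signal SNPs at 0.4 log-odds per
    dosage unit, a 15% sub-class driven by 15 distinct SNPs at 0.6
    log-odds, and a sprinkling of QC failures.
    """

    n_founder_cases: int = 1100
    n_founder_controls: int = 1100
    relatives_per_case: int = 0
    n_snps: int = 20000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_causal_main: int = 20
    beta_main: float = 0.4
    n_causal_sub: int = 15
    beta_sub: float = 0.6
    subclass_fraction: float = 0.15
    fst: float = 0.05
    pop2_fraction: float = 0.1
    missing_rate: float = 0.001
    n_monomorphic: int = 50
    n_hwe_violating: int = 20
    hwe_inbreeding: float = 0.8
    n_high_missing: int = 40
    n_no_rsid: int = 30
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.fst < 0.5):
            raise ConfigurationError(f"fst must be in [0, 0.5), got {self.fst}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.relatives_per_case not in (0, 1, 2):
            raise ConfigurationError("relatives_per_case must be 0, 1 or 2")
        if not (0 <= self.subclass_fraction < 1):
            raise ConfigurationError("subclass_fraction must be in [0, 1)")
        for name in ("pop2_fraction", "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not (0 < self.hwe_inbreeding <= 1):
            raise ConfigurationError("hwe_inbreeding must be in (0, 1]")
        planted = (self.n_causal_main + self.n_causal_sub + self.n_monomorphic
                   + self.n_hwe_violating + self.n_high_missing + self.n_no_rsid)
        if planted > self.n_snps:
            raise ConfigurationError(
                f"causal + planted-failure SNP counts ({planted}) exceed n_snps ({self.n_snps})"
            )
        if min(self.n_founder_cases, self.n_founder_controls) < 0:
            raise ConfigurationError("founder counts must be non-negative")
        if self.n_founder_cases + self.n_founder_controls < 1:
            raise ConfigurationError("need at least one founder")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        cfg = cls(**d)
        if isinstance(cfg.maf_range, list):
            cfg.maf_range = tuple(cfg.maf_range)
        cfg.validate()
        return cfg


@dataclass
class PhenotypeModel:
    """Frozen generative phenotype model: which SNPs drive which subjects."""

    main_idx: np.ndarray
    sub_idx: np.ndarray
    beta_main: float
    beta_sub: float
    alpha_main: float
    alpha_sub: float
    subclass_fraction: float

    def linear_predictor(self, dosages: np.ndarray, subclass: np.ndarray) -> np.ndarray:
        s_main = dosages[:, self.main_idx].sum(axis=1).astype(float)
        s_sub = dosages[:, self.sub_idx].sum(axis=1).astype(float) if len(self.sub_idx) else np.zeros(len(dosages))
        eta = self.alpha_main + self.beta_main * s_main
        eta_sub = self.alpha_sub + self.beta_sub * s_sub
        return np.where(subclass, eta_sub, eta)

    def case_probability(self, dosages: np.ndarray, subclass: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(dosages, subclass))


@dataclass
class TruthManifest:
    """Ground truth of a generated cohort, for validation and audit."""

    main_causal_snps: List[str]
    sub_causal_snps: List[str]
    subclass_members: List[str]
    population_of: Dict[str, int]
    planted_failures: Dict[str, List[str]]
    kinship_true: Optional["KinshipMatrix"] = None  # noqa: F821 (assoc import cycle)
    phenotype_model: Optional[PhenotypeModel] = None

    def validate(self) -> None:
        main = set(self.main_causal_snps)
        sub = set(self.sub_causal_snps)
        if main & sub:
            raise GenerationError("main and sub-class causal SNP sets overlap")
        causal = main | sub
        fail_sets = {k: set(v) for k, v in self.planted_failures.items()}
        for kind, ids in fail_sets.items():
            if ids & causal:
                raise GenerationError(f"planted {kind} failures overlap causal SNPs")
        kinds = list(fail_sets)
        for i, a in enumerate(kinds):
            for b in kinds[i + 1:]:
                if fail_sets[a] & fail_sets[b]:
                    raise GenerationError(f"planted failure sets {a} and {b} overlap")

    def to_json(self, path) -> None:
        payload = {
            "main_causal_snps": sorted(self.main_causal_snps),
            "sub_causal_snps": sorted(self.sub_causal_snps),
            "subclass_members": sorted(self.subclass_members),
            "population_of": dict(sorted(self.population_of.items())),
            "planted_failures": {k: sorted(v) for k, v in sorted(self.planted_failures.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# allele frequencies and founder genotypes


def draw_allele_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP, per-population allele frequencies (shape ``(2, n_snps)``).

    Ancestral frequencies are uniform on ``maf_range``; each population's
    frequency is Beta-distributed around the ancestral value with
    Balding-Nichols parameters ``p(1-fst)/fst`` and ``(1-p)(1-fst)/fst``,
    so the cross-population variance of the frequency is ``fst * p(1-p)``.
    With ``fst = 0`` the populations coincide exactly.
    """
    config.validate()
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n_snps)
    if config.fst == 0:
        return np.vstack([p, p])
    a = p * (1 - config.fst) / config.fst
    b = (1 - p) * (1 - config.fst) / config.fst
    freqs = rng.beta(np.vstack([a, a]), np.vstack([b, b]))
    # keep frequencies in the open interval to avoid degenerate SNPs
    return np.clip(freqs, 1e-6, 1 - 1e-6)


def _make_snp_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_snps
    weights = _CHROM_MB / _CHROM_MB.sum()
    counts = np.floor(weights * m).astype(int)
    remainder = m - counts.sum()
    order = np.argsort(-(weights * m - counts))
    counts[order[:remainder]] += 1
    chroms = np.repeat(np.arange(1, 23), counts)
    pos = np.empty(m, dtype=int)
    start = 0
    for c in range(1, 23):
        k = counts[c - 1]
        span = int(_CHROM_MB[c - 1] * 1_000_000)
        draw = np.unique(rng.integers(0, span, size=2 * k + 16))
        while len(draw) < k:  # vanishingly unlikely top-up
            draw = np.unique(np.concatenate([draw, rng.integers(0, span, size=k)]))
        pos[start:start + k] = np.sort(rng.choice(draw, size=k, replace=False)) + 1
        start += k
    return pd.DataFrame({
        "chrom": chroms,
        "snp": [f"rs{i + 1}" for i in range(m)],
        "cm": 0.0,
        "pos": pos,
        "a1": "A",
        "a2": "G",
    })[SNP_COLUMNS]


def simulate_genotypes(frequencies: np.ndarray, config: SimConfig,
                       rng: np.random.Generator) -> Tuple[GenotypeData, np.ndarray]:
    """Draw founder genotypes; returns the cohort and population labels (1/2)."""
    n = config.n_founder_cases + config.n_founder_controls
    pop = np.where(rng.random(n) < config.pop2_fraction, 2, 1)
    m = frequencies.shape[1]
    p_per_sample = frequencies.astype(np.float32)[pop - 1]  # (n, m)
    # binomial(2, p) as a sum of two Bernoulli draws; float32 uniforms halve
    # the memory traffic, which dominates at cohort scale
    dosages = np.empty((n, m), dtype=np.int8)
    dosages[:] = rng.random((n, m), dtype=np.float32) < p_per_sample
    dosages += rng.random((n, m), dtype=np.float32) < p_per_sample
    samples = pd.DataFrame({
        "fid": [f"F{i:05d}" for i in range(n)],
        "iid": [f"I{i:05d}" for i in range(n)],
        "father": "0",
        "mother": "0",
        "sex": 1,
        "phenotype": 0,
    })[SAMPLE_COLUMNS]
    snps = _make_snp_table(config, rng)
    return GenotypeData(dosages, snps, samples), pop


# ---------------------------------------------------------------------------
# phenotypes


def _solve_intercept(beta: float, scores: np.ndarray, target: float,
                     tol: float = 1e-6) -> float:
    """Bisection for alpha with mean(expit(alpha + beta*scores)) = target."""
    if len(scores) == 0:
        return 0.0

    def share(alpha: float) -> float:
        return float(np.mean(expit(alpha + beta * scores)))

    lo, hi = -60.0, 60.0
    s_lo, s_hi = share(lo), share(hi)
    if target < s_lo - tol or target > s_hi + tol:
        raise GenerationError(
            f"target case share {target} unattainable with beta={beta}"
        )
    # degenerate targets (all-control / all-case cohorts): clamp to the
    # bracket edge, where the residual probability is ~1e-26 per subject
    if target <= s_lo:
        return lo
    if target >= s_hi:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if share(mid) < target:
            lo = mid
        else:
            hi = mid
        if abs(share(mid) - target) < tol:
            return mid
    return 0.5 * (lo + hi)


def assign_phenotypes(
    genotypes: GenotypeData,
    config: SimConfig,
    rng: np.random.Generator,
    model: Optional[PhenotypeModel] = None,
) -> Tuple[np.ndarray, np.ndarray, PhenotypeModel]:
    """Assign case/control labels from genotype.

    A ``subclass_fraction`` share of subjects is flagged sub-class; their
    case probability depends only on the sub-class causal SNPs, everyone
    else's only on the main causal SNPs.  Intercepts are solved by
    bisection so each group's expected case share equals the configured
    case:control balance.  Returns ``(phenotypes in {1,2}, subclass mask,
    model)``.  Pass ``model`` to reuse frozen causal sets/intercepts (for
    relatives).
    """
    n = genotypes.n_samples
    target = config.n_founder_cases / (config.n_founder_cases + config.n_founder_controls)
    subclass = rng.random(n) < config.subclass_fraction
    if model is None:
        eligible = np.arange(genotypes.n_snps)
        chosen = rng.choice(eligible, size=config.n_causal_main + config.n_causal_sub,
                            replace=False)
        main_idx = np.sort(chosen[:config.n_causal_main])
        sub_idx = np.sort(chosen[config.n_causal_main:])
        d = genotypes.dosages.astype(float)
        s_main = d[:, main_idx].sum(axis=1)
        s_sub = d[:, sub_idx].sum(axis=1) if len(sub_idx) else np.zeros(n)
        alpha_main = _solve_intercept(config.beta_main, s_main[~subclass], target)
        alpha_sub = (_solve_intercept(config.beta_sub, s_sub[subclass], target)
                     if subclass.any() else 0.0)
        model = PhenotypeModel(main_idx, sub_idx, config.beta_main, config.beta_sub,
                               alpha_main, alpha_sub, config.subclass_fraction)
    prob = model.case_probability(genotypes.dosages.astype(float), subclass)
    phenotypes = np.where(rng.random(n) < prob, 2, 1)
    return phenotypes, subclass, model


# ---------------------------------------------------------------------------
# families


def _sample_parent_pairs(child: np.ndarray, p: np.ndarray,
                         rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Sample parental dosage pairs conditional on an observed child.

    Per SNP, the pair (g_mother, g_father) is drawn from its exact
    posterior under Hardy-Weinberg parents and Mendelian transmission,
    so the child keeps its genotype and siblings drawn from the same
    parents have the textbook 0.25 kinship with it.
    """
    m = len(child)
    # transmission probability P(child dosage | gm, gf)
    trans = np.zeros((3, 3, 3))
    for gm in range(3):
        for gf in range(3):
            tm, tf = gm / 2.0, gf / 2.0
            trans[gm, gf, 2] = tm * tf
            trans[gm, gf, 1] = tm * (1 - tf) + (1 - tm) * tf
            trans[gm, gf, 0] = (1 - tm) * (1 - tf)
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])  # (3, m)
    prior = hwe[:, None, :] * hwe[None, :, :]  # (gm, gf, m)
    like = trans[:, :, child]  # (gm, gf, m)
    post = prior * like
    post = post.reshape(9, m)
    total = post.sum(axis=0)
    total[total == 0] = 1.0  # impossible child under p in (0,1) cannot occur
    post /= total
    u = rng.random(m)
    idx = (post.cumsum(axis=0) < u).sum(axis=0)
    idx = np.minimum(idx, 8)
    return (idx // 3).astype(np.int8), (idx % 3).astype(np.int8)


def _mendelian_child(gm: np.ndarray, gf: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    a = rng.random(gm.shape) < gm / 2.0
    b = rng.random(gf.shape) < gf / 2.0
    return (a.astype(np.int8) + b.astype(np.int8))


def simulate_families(
    founders: GenotypeData,
    config: SimConfig,
    frequencies: np.ndarray,
    populations: np.ndarray,
    rng: np.random.Generator,
) -> Tuple[GenotypeData, Pedigree, np.ndarray, "KinshipMatrix"]:  # noqa: F821
    """Add full siblings for each affected founder.

    For every case founder, two parents are sampled conditional on the
    founder's genotype (Hardy-Weinberg priors at the founder's population
    frequencies), and ``relatives_per_case`` siblings are drawn by
    Mendelian transmission.  Parents appear in the pedigree (as founders)
    but not in the genotype cohort.  Returns the extended cohort, the
    pedigree, the extended population vector and the true kinship matrix
    over cohort members (0.5 diagonal, 0.25 for full sibs, 0 otherwise).
    """
    from .assoc import KinshipMatrix

    n0 = founders.n_samples
    affected = np.flatnonzero(founders.samples["phenotype"].to_numpy() == 2)
    rows = [founders.dosages]
    sample_rows: List[dict] = []
    ped_rows: List[dict] = []
    pops = list(populations)
    sib_groups: List[List[int]] = []

    founder_records = founders.samples
    for i in range(n0):
        rec = founder_records.iloc[i]
        ped_rows.append(dict(fid=rec.fid, iid=rec.iid, father="0", mother="0"))

    next_row = n0
    if config.relatives_per_case > 0 and len(affected):
        for i in affected:
            rec = founder_records.iloc[i]
            p = frequencies[populations[i] - 1]
            gm, gf = _sample_parent_pairs(founders.dosages[i], p, rng)
            mother_id, father_id = f"{rec.iid}M", f"{rec.iid}P"
            ped_rows.append(dict(fid=rec.fid, iid=father_id, father="0", mother="0"))
            ped_rows.append(dict(fid=rec.fid, iid=mother_id, father="0", mother="0"))
            # re-attach the founder to its parents
            for row in ped_rows:
                if row["iid"] == rec.iid:
                    row["father"], row["mother"] = father_id, mother_id
            group = [i]
            for k in range(config.relatives_per_case):
                sib = _mendelian_child(gm, gf, rng)
                rows.append(sib[None, :])
                iid = f"{rec.iid}S{k + 1}"
                sample_rows.append(dict(fid=rec.fid, iid=iid, father=father_id,
                                        mother=mother_id, sex=1, phenotype=0))
                ped_rows.append(dict(fid=rec.fid, iid=iid, father=father_id,
                                     mother=mother_id))
                pops.append(populations[i])
                group.append(next_row)
                next_row += 1
            sib_groups.append(group)

    dosages = np.vstack(rows)
    samples = pd.concat(
        [founder_records, pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)],
        ignore_index=True,
    ) if sample_rows else founder_records.copy()
    cohort = GenotypeData(dosages, founders.snps.copy(), samples)

    n = cohort.n_samples
    phi = np.zeros((n, n))
    np.fill_diagonal(phi, 0.5)
    for group in sib_groups:
        for a_i, a in enumerate(group):
            for b in group[a_i + 1:]:
                phi[a, b] = phi[b, a] = 0.25
    kinship = KinshipMatrix(phi, list(cohort.samples["iid"]))
    pedigree = Pedigree(pd.DataFrame(ped_rows, columns=["fid", "iid", "father", "mother"]))
    return cohort, pedigree, np.asarray(pops), kinship


# ---------------------------------------------------------------------------
# planted QC failures


def plant_qc_failures(
    genotypes: GenotypeData,
    config: SimConfig,
    rng: np.random.Generator,
    protected_idx: np.ndarray,
    ancestral_p: np.ndarray,
) -> Tuple[GenotypeData, Dict[str, List[str]]]:
    """Overwrite designated non-causal SNPs with QC failures.

    monomorphic: all dosage 0; hwe: genotypes redrawn with inbreeding
    coefficient ``hwe_inbreeding`` at the SNP's ancestral frequency;
    high_missing: per-SNP missing rate drawn uniformly in [0.05, 0.10];
    no_rsid: identifier replaced by a chrom:pos name.  Background
    missingness at ``missing_rate`` is applied everywhere else.
    """
    data = genotypes.copy()
    n, m = data.dosages.shape
    free = np.setdiff1d(np.arange(m), protected_idx)
    n_needed = (config.n_monomorphic + config.n_hwe_violating
                + config.n_high_missing + config.n_no_rsid)
    if n_needed > len(free):
        raise GenerationError("not enough non-causal SNPs for planted failures")
    chosen = rng.choice(free, size=n_needed, replace=False)
    c = np.cumsum([config.n_monomorphic, config.n_hwe_violating,
                   config.n_high_missing, config.n_no_rsid])
    mono_idx = np.sort(chosen[:c[0]])
    hwe_idx = np.sort(chosen[c[0]:c[1]])
    miss_idx = np.sort(chosen[c[1]:c[2]])
    norsid_idx = np.sort(chosen[c[2]:c[3]])

    data.dosages[:, mono_idx] = 0

    for j in hwe_idx:
        p = float(ancestral_p[j])
        f = config.hwe_inbreeding
        probs = np.array([
            (1 - p) ** 2 + f * p * (1 - p),   # dosage 0
            2 * p * (1 - p) * (1 - f),        # dosage 1
            p ** 2 + f * p * (1 - p),         # dosage 2
        ])
        data.dosages[:, j] = rng.choice(3, size=n, p=probs).astype(np.int8)

    # background missingness first, excluding the planted high-missing columns
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        mask[:, miss_idx] = False
        mask[:, mono_idx] = False  # keep monomorphic columns fully observed
        data.dosages[mask] = MISSING

    rates = rng.uniform(0.05, 0.10, size=len(miss_idx))
    for j, rate in zip(miss_idx, rates):
        cells = rng.random(n) < rate
        data.dosages[cells, j] = MISSING

    snp_ids = data.snps["snp"].to_numpy().copy()
    for j in norsid_idx:
        snp_ids[j] = f"chr{data.snps['chrom'][j]}:{data.snps['pos'][j]}"
    data.snps["snp"] = snp_ids

    ids = data.snps["snp"]
    planted = {
        "monomorphic": list(ids.iloc[mono_idx]),
        "hwe": list(ids.iloc[hwe_idx]),
        "high_missing": list(ids.iloc[miss_idx]),
        "no_rsid": list(ids.iloc[norsid_idx]),
    }
    return data, planted


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SyntheticCohort:
    genotypes: GenotypeData
    pedigree: Pedigree
    truth: TruthManifest


def generate_cohort(config: SimConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground-truth manifest.

    The pipeline: allele frequencies -> founder genotypes -> founder
    phenotypes -> siblings of affected founders (with genotype-driven
    phenotypes from the same frozen model) -> planted QC failures and
    background missingness.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    r_freq, r_geno, r_pheno, r_fam, r_sibpheno, r_plant = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    freqs = draw_allele_frequencies(config, r_freq)
    ancestral_p = freqs.mean(axis=0)
    founders, pop = simulate_genotypes(freqs, config, r_geno)
    phen, subclass, model = assign_phenotypes(founders, config, r_pheno)
    founders.samples["phenotype"] = phen

    cohort, pedigree, pop_all, kinship = simulate_families(
        founders, config, freqs, pop, r_fam
    )
    n0 = founders.n_samples
    if cohort.n_samples > n0:
        relatives = cohort.subset_samples(np.arange(n0, cohort.n_samples))
        rel_phen, rel_sub, _ = assign_phenotypes(relatives, config, r_sibpheno, model=model)
        phen_all = np.concatenate([phen, rel_phen])
        subclass_all = np.concatenate([subclass, rel_sub])
        cohort.samples["phenotype"] = phen_all
    else:
        subclass_all = subclass

    snp_ids_pre = cohort.snps["snp"].to_numpy()
    main_ids = list(snp_ids_pre[model.main_idx])
    sub_ids = list(snp_ids_pre[model.sub_idx])
    protected = np.concatenate([model.main_idx, model.sub_idx]).astype(int)
    cohort, planted = plant_qc_failures(cohort, config, r_plant, protected, ancestral_p)
    # orient dosages to the realized minor allele so written files read back
    # unchanged (a pure relabeling; phenotypes are already assigned)
    from .genio import _canonical_minor_orientation
    cohort = _canonical_minor_orientation(cohort)

    iids = cohort.samples["iid"].to_numpy()
    truth = TruthManifest(
        main_causal_snps=main_ids,
        sub_causal_snps=sub_ids,
        subclass_members=list(iids[subclass_all]),
        population_of={iid: int(p) for iid, p in zip(iids, pop_all)},
        planted_failures=planted,
        kinship_true=kinship,
        phenotype_model=model,
    )
    truth.validate()
    return SyntheticCohort(cohort, pedigree, truth)
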