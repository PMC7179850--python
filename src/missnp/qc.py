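"""Subject- and SNP-level quality control.

The cascade mirrors standard GWAS practice: drop subjects with unclear
phenotype, remove ancestry outliers with an EIGENSTRAT-style PCA, reduce
to one subject per family for model building, and filter SNPs by
chromosome, rs identifier, call rate, monomorphism and Hardy-Weinberg
equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeData, Pedigree


class QCError(RuntimeError):
    """Raised when a QC stage leaves no usable data."""


@dataclass
class QCStage:
    name: str
    unit: str  # "subjects" or "snps"
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class QCReport:
    """Per-stage bookkeeping: entering - removed = retained, every stage."""

    stages: List[QCStage] = field(default_factory=list)
    removed_ids: Dict[str, List[str]] = field(default_factory=dict)

    def add(self, name: str, unit: str, n_in: int, removed: List[str]) -> None:
        self.stages.append(QCStage(name, unit, n_in, len(removed)))
        self.removed_ids[name] = list(removed)

    def removed_count(self, name: str) -> int:
        for s in self.stages:
            if s.name == name:
                return s.n_removed
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "unit": s.unit, "in": s.n_in,
                 "removed": s.n_removed, "out": s.n_out}
                for s in self.stages
            ],
        }


# ---------------------------------------------------------------------------
# subjects


def filter_phenotype(data: GenotypeData, report: Optional[QCReport] = None
                     ) -> Tuple[GenotypeData, QCReport]:
    """Remove subjects whose phenotype code is not 1 (control) or 2 (case)."""
    report = report or QCReport()
    phen = data.samples["phenotype"].to_numpy()
    keep = np.isin(phen, (1, 2))
    removed = list(data.samples.loc[~keep, "iid"])
    report.add("phenotype", "subjects", data.n_samples, removed)
    out = data.subset_samples(keep)
    if out.n_samples == 0:
        raise QCError("no subjects remain after phenotype filtering")
    return out, report


def _sample_snps_by_chromosome(snps: pd.DataFrame, n_snps: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Sample SNP row positions without replacement, with per-chromosome
    quotas proportional to each chromosome's SNP count."""
    total = len(snps)
    if total <= n_snps:
        return np.arange(total)
    chosen: List[np.ndarray] = []
    groups = snps.groupby("chrom", sort=True).indices
    counts = {c: len(ix) for c, ix in groups.items()}
    quotas = {c: int(np.floor(n_snps * cnt / total)) for c, cnt in counts.items()}
    short = n_snps - sum(quotas.values())
    fracs = sorted(
        groups, key=lambda c: -(n_snps * counts[c] / total - quotas[c])
    )
    for c in fracs[:short]:
        quotas[c] += 1
    for c, ix in groups.items():
        take = min(quotas[c], len(ix))
        chosen.append(rng.choice(ix, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


def pca_ancestry_filter(
    data: GenotypeData,
    n_snps: int = 100_000,
    n_pcs: int = 2,
    pc1_threshold: float = 0.0,
    per_group: bool = True,
    seed: Optional[int] = 0,
    separation_cutoff: float = 3.0,
    report: Optional[QCReport] = None,
) -> Tuple[GenotypeData, pd.DataFrame, QCReport]:
    """EIGENSTRAT-style ancestry filtering on the first principal component.

    A random SNP subsample (per-chromosome quotas proportional to
    chromosome SNP counts) is variance-standardized as
    ``(g - mu) / sqrt(p(1-p))`` with missing cells zeroed after
    centering; the top sample-space PCs are computed, and within each
    phenotype group the side of ``pc1_threshold`` holding the majority is
    retained.  If PC1 shows no cluster separation (two-means split with
    between/within separation below ``separation_cutoff``), the cohort is
    judged homogeneous and nobody is removed.

    Returns (retained data, PC coordinates indexed by iid, report).
    """
    report = report or QCReport()
    if data.n_samples < n_pcs:
        raise QCError(f"need at least {n_pcs} samples for {n_pcs} PCs")
    rng = np.random.default_rng(seed)
    cols = _sample_snps_by_chromosome(data.snps, n_snps, rng)

    d = data.dosages[:, cols]
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    sums = np.where(obs, d, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = sums / n_obs
    p = mu / 2.0
    denom = np.sqrt(p * (1 - p))
    usable = np.isfinite(denom) & (denom > 0)
    if not usable.any():
        raise QCError("all sampled SNPs are monomorphic; PCA undefined")
    scale = np.zeros(len(denom), dtype=np.float32)
    scale[usable] = 1.0 / denom[usable]
    M = d.astype(np.float32)
    M -= mu.astype(np.float32)
    M[~obs] = 0.0  # missing cells contribute nothing after centering
    M *= scale
    M = M[:, usable]

    n = data.n_samples
    if n * M.shape[1] <= 2_000_000:
        # exact eigendecomposition of the sample-space Gram matrix
        from scipy.linalg import eigh as scipy_eigh

        G = (M @ M.T).astype(np.float64) / M.shape[1]
        eigval, eigvec = scipy_eigh(G, subset_by_index=[n - n_pcs, n - 1])
        order = np.argsort(eigval)[::-1]
        coords = eigvec[:, order] * np.sqrt(np.maximum(eigval[order], 0.0))
    else:
        # randomized SVD: avoids the O(n^2 m) Gram product, which dominates
        # the whole QC stage at cohort scale; seeded, hence deterministic
        from sklearn.utils.extmath import randomized_svd

        U, s, _ = randomized_svd(M, n_components=n_pcs, n_oversamples=10,
                                 n_iter=7, random_state=rng.integers(2 ** 31))
        coords = U * (s / np.sqrt(M.shape[1]))
    coord_df = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(n_pcs)],
        index=pd.Index(data.samples["iid"], name="iid"),
    )

    pc1 = coords[:, 0]
    if _pc1_separation(pc1) < separation_cutoff:
        keep = np.ones(data.n_samples, dtype=bool)
    else:
        keep = np.zeros(data.n_samples, dtype=bool)
        phen = data.samples["phenotype"].to_numpy()
        groups = [phen == 2, phen == 1] if per_group else [np.ones_like(pc1, bool)]
        for g in groups:
            if not g.any():
                continue
            positive = pc1[g] > pc1_threshold
            majority_positive = positive.mean() >= 0.5
            keep[g] = positive == majority_positive

    removed = list(data.samples.loc[~keep, "iid"])
    report.add("ancestry_pca", "subjects", data.n_samples, removed)
    out = data.subset_samples(keep)
    if out.n_samples == 0:
        raise QCError("no subjects remain after ancestry filtering")
    return out, coord_df, report


def _pc1_separation(pc1: np.ndarray) -> float:
    """Two-means split of PC1; |mean gap| / pooled within-cluster sd."""
    lo, hi = pc1.min(), pc1.max()
    if hi == lo:
        return 0.0
    c1, c2 = lo, hi
    for _ in range(50):
        mid = 0.5 * (c1 + c2)
        left = pc1 <= mid
        if not left.any() or left.all():
            return 0.0
        n1, n2 = c1, c2
        c1, c2 = pc1[left].mean(), pc1[~left].mean()
        if np.isclose(c1, n1) and np.isclose(c2, n2):
            break
    left = pc1 <= 0.5 * (c1 + c2)
    within = np.concatenate([pc1[left] - pc1[left].mean(),
                             pc1[~left] - pc1[~left].mean()])
    sd = within.std()
    if sd == 0:
        return np.inf
    return float(abs(c2 - c1) / sd)


def select_unrelated(
    data: GenotypeData,
    pedigree: Optional[Pedigree] = None,
    seed: Optional[int] = 0,
    report: Optional[QCReport] = None,
) -> Tuple[GenotypeData, QCReport]:
    """Keep exactly one subject per family, chosen uniformly at random."""
    report = report or QCReport()
    rng = np.random.default_rng(seed)
    fids = data.samples["fid"].to_numpy()
    keep = np.zeros(data.n_samples, dtype=bool)
    for _, idx in pd.Series(np.arange(data.n_samples)).groupby(fids, sort=True):
        keep[rng.choice(idx.to_numpy())] = True
    removed = list(data.samples.loc[~keep, "iid"])
    report.add("one_per_family", "subjects", data.n_samples, removed)
    return data.subset_samples(keep), report


# ---------------------------------------------------------------------------
# SNPs


def snp_qc(
    data: GenotypeData,
    autosomes_only: bool = True,
    require_rsid: bool = True,
    min_call_rate: float = 0.98,
    hwe_alpha: float = 1e-5,
    drop_monomorphic: bool = True,
    hwe_on: str = "controls",
    hwe_exact: bool = False,
    report: Optional[QCReport] = None,
) -> Tuple[GenotypeData, QCReport]:
    """SNP quality-control cascade, applied in the documented order.

    1. autosomes only (chromosome code <= 22);
    2. rs identifier required;
    3. call rate: fraction of non-missing calls computed within cases and
       within controls separately; removed if strictly below
       ``min_call_rate`` in either group (a SNP at exactly the threshold
       is retained);
    4. monomorphic: a single observed genotype value among non-missing
       calls (all-missing SNPs are removed here too);
    5. Hardy-Weinberg: chi-square test in the ``hwe_on`` group
       ('controls', 'cases' or 'all'), removed if p strictly below
       ``hwe_alpha``.
    """
    report = report or QCReport()

    def apply(name: str, keep: np.ndarray, d: GenotypeData) -> GenotypeData:
        removed = list(d.snps.loc[~keep, "snp"])
        report.add(name, "snps", d.n_snps, removed)
        return d.subset_snps(keep)

    if autosomes_only:
        keep = data.snps["chrom"].to_numpy() <= 22
        data = apply("autosomes", keep, data)

    if require_rsid:
        keep = data.snps["snp"].str.startswith("rs").to_numpy()
        data = apply("rsid", keep, data)

    phen = data.samples["phenotype"].to_numpy()
    is_case = phen == 2
    is_ctrl = phen == 1

    if min_call_rate is not None:
        obs = data.dosages != MISSING
        keep = np.ones(data.n_snps, dtype=bool)
        for group in (is_case, is_ctrl):
            if group.any():
                rate = obs[group].mean(axis=0)
                keep &= rate >= min_call_rate
        data = apply("call_rate", keep, data)

    if drop_monomorphic:
        obs = data.dosages != MISSING
        n_values = np.zeros(data.n_snps, dtype=int)
        for v in (0, 1, 2):
            n_values += ((data.dosages == v) & obs).any(axis=0)
        keep = n_values >= 2
        data = apply("monomorphic", keep, data)

    if hwe_alpha is not None:
        group = {"controls": is_ctrl, "cases": is_case,
                 "all": np.ones(len(phen), bool)}[hwe_on]
        # sample masks stay valid across SNP filters (sample axis untouched)
        sub = data.subset_samples(group) if not group.all() else data
        from .assoc import hwe_scan

        pvals = hwe_scan(sub, exact=hwe_exact)
        keep = pvals >= hwe_alpha
        data = apply("hwe", keep, data)

    if data.n_snps == 0:
        raise QCError("no SNPs remain after QC")
    return data, report
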