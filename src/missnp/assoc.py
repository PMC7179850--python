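"""Association statistics: pedigree kinship, Hardy-Weinberg tests and the
kinship-corrected chi-square case-control test used for SNP pre-selection.

The corrected test is the quasi-likelihood variance correction of the
classical allelic trend statistic: with case/control contrast weights
``w`` (``1/n_case`` for cases, ``-1/n_ctrl`` for controls) and dosage
vector ``X``, the score is ``D = w'X`` and, using the dosage covariance
``Cov(X_i, X_j) = 4 phi_ij p(1-p)`` implied by kinship coefficients
``phi``, its variance estimate is ``2 p(1-p) * w'(2 Phi) w``.  The
statistic ``D^2 / Var(D)`` is chi-square with 1 df and reduces exactly to
the classical unrelated-samples test when ``Phi = 0.5 I``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genio import MISSING, GenotypeData, Pedigree


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (cycles, dangling parents)."""


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship coefficients with sample identifiers."""

    values: np.ndarray
    ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def is_unrelated(self) -> bool:
        """True when the matrix is exactly 0.5 * identity."""
        return bool(
            np.all(np.diag(self.values) == 0.5)
            and np.count_nonzero(self.values) == len(self.ids)
        )

    @classmethod
    def identity(cls, ids: Sequence[str]) -> "KinshipMatrix":
        return cls(0.5 * np.eye(len(ids)), list(ids))

    def subset(self, ids: Iterable[str]) -> "KinshipMatrix":
        ids = [str(i) for i in ids]
        index = pd.Index(self.ids).get_indexer(ids)
        if (index < 0).any():
            missing = [i for i, p in zip(ids, index) if p < 0]
            raise KeyError(f"samples absent from kinship matrix: {missing[:5]}")
        return KinshipMatrix(self.values[np.ix_(index, index)], ids)


def kinship_from_pedigree(pedigree: Pedigree) -> KinshipMatrix:
    """Kinship coefficients by the recursive tabular method.

    Individuals are processed parents-before-children; founders are
    unrelated with ``phi_ii = 0.5``.  For individual ``i`` with parents
    ``f, m``: ``phi_ii = 0.5 (1 + phi_fm)`` and, against any earlier
    individual ``j``, ``phi_ij = 0.5 (phi_fj + phi_mj)`` with unknown
    parents contributing zero.
    """
    t = pedigree.table.astype(str)
    ids = list(t["iid"])
    father = dict(zip(t["iid"], t["father"]))
    mother = dict(zip(t["iid"], t["mother"]))

    # topological order (Kahn); a cycle leaves nodes unprocessed
    children: dict = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for i in ids:
        for parent in (father[i], mother[i]):
            if parent != "0":
                children[parent].append(i)
                indeg[i] += 1
    queue = [i for i in ids if indeg[i] == 0]
    order: List[str] = []
    while queue:
        node = queue.pop()
        order.append(node)
        for child in children[node]:
            indeg[child] -= 1
            if indeg[child] == 0:
                queue.append(child)
    if len(order) != len(ids):
        raise PedigreeError("pedigree contains a cycle")

    n = len(ids)
    pos = {iid: k for k, iid in enumerate(order)}
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        f, m = father[iid], mother[iid]
        fi = pos.get(f, -1) if f != "0" else -1
        mi = pos.get(m, -1) if m != "0" else -1
        phi_fm = phi[fi, mi] if fi >= 0 and mi >= 0 else 0.0
        phi[k, k] = 0.5 * (1.0 + phi_fm)
        for j in range(k):
            val = 0.0
            if fi >= 0:
                val += 0.5 * phi[fi, j]
            if mi >= 0:
                val += 0.5 * phi[mi, j]
            phi[k, j] = phi[j, k] = val

    # return in the pedigree's original id order
    perm = np.array([pos[i] for i in ids])
    return KinshipMatrix(phi[np.ix_(perm, perm)], ids)


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_test(n_aa2: int, n_het: int, n_aa0: int, exact: bool = False):
    """Hardy-Weinberg goodness-of-fit test from genotype counts.

    Arguments are the counts of dosage-2 homozygotes, heterozygotes and
    dosage-0 homozygotes.  Returns ``(statistic, p)``; a monomorphic
    input gives ``(0.0, 1.0)`` by convention.  ``exact=True`` uses the
    exact conditional test instead of the 1-df chi-square.
    """
    counts = np.array([n_aa2, n_het, n_aa0], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p_hat = (2 * counts[0] + counts[1]) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0
    if exact:
        return _hwe_exact(int(n_aa2), int(n_het), int(n_aa0))
    expected = n * np.array([p_hat ** 2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
    stat = float(((counts - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def _hwe_exact(n2: int, n1: int, n0: int):
    """Exact HWE test (sum of probabilities <= observed, conditional on
    allele counts); returns (heterozygote excess statistic, p)."""
    n = n2 + n1 + n0
    na = 2 * n2 + n1  # copies of the dosage allele
    from scipy.special import gammaln

    def log_prob(het: int) -> float:
        hom2 = (na - het) // 2
        hom0 = n - hom2 - het
        return (
            gammaln(n + 1) - gammaln(hom2 + 1) - gammaln(het + 1) - gammaln(hom0 + 1)
            + het * np.log(2.0)
            + gammaln(na + 1) + gammaln(2 * n - na + 1) - gammaln(2 * n + 1)
        )

    hets = np.arange(na % 2, min(na, 2 * n - na) + 1, 2)
    logp = np.array([log_prob(int(h)) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n1][0]
    p_val = float(probs[probs <= p_obs + 1e-12].sum())
    return float(n1), min(1.0, p_val)


def hwe_scan(data: GenotypeData, exact: bool = False) -> np.ndarray:
    """Per-SNP HWE p-values over all samples of ``data``."""
    d = data.dosages
    obs = d != MISSING
    n2 = ((d == 2) & obs).sum(axis=0)
    n1 = ((d == 1) & obs).sum(axis=0)
    n0 = ((d == 0) & obs).sum(axis=0)
    if exact:
        out = np.empty(data.n_snps)
        for j in range(data.n_snps):
            out[j] = hwe_test(int(n2[j]), int(n1[j]), int(n0[j]), exact=True)[1]
        return out
    counts = np.stack([n2, n1, n0]).astype(float)  # (3, m)
    n = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = (2 * counts[0] + counts[1]) / (2 * n)
        expected = n * np.stack([p_hat ** 2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
        stat = np.nansum((counts - expected) ** 2 / expected, axis=0)
    mono = (p_hat <= 0) | (p_hat >= 1) | (n == 0) | ~np.isfinite(p_hat)
    stat = np.where(mono, 0.0, stat)
    return np.where(mono, 1.0, chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# kinship-corrected chi-square


def corrected_chi2(
    dosages: np.ndarray,
    is_case: np.ndarray,
    kinship: KinshipMatrix | None = None,
    chunk: int = 4096,
):
    """Kinship-corrected chi-square trend statistic per SNP.

    Parameters
    ----------
    dosages : (n,) or (n, m) array
        Minor-allele dosages; ``-1`` or NaN marks missing (excluded
        pairwise: both the contrast and the kinship quadratic form are
        restricted to samples called at that SNP).
    is_case : (n,) boolean array
    kinship : KinshipMatrix or None
        ``None`` means unrelated samples (``Phi = 0.5 I`` fast path).

    Returns ``(stat, p)`` arrays (scalars for a single SNP).
    """
    X = np.asarray(dosages, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[:, None]
    X = X.copy()
    X[X == MISSING] = np.nan
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.all() or (~is_case).all():
        raise ValueError("both cases and controls are required")
    n, m = X.shape

    obs = ~np.isnan(X)
    n_case = (obs & is_case[:, None]).sum(axis=0).astype(float)
    n_ctrl = (obs & ~is_case[:, None]).sum(axis=0).astype(float)
    usable = (n_case > 0) & (n_ctrl > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(is_case[:, None], 1.0 / n_case, -1.0 / n_ctrl)
    W = np.where(obs, W, 0.0)
    Xf = np.nan_to_num(X)
    D = (W * Xf).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_hat = np.nansum(Xf, axis=0) / (2.0 * (n_case + n_ctrl))

    unrelated = kinship is None or kinship.is_unrelated
    if unrelated:
        quad = (W ** 2).sum(axis=0)
    else:
        K2 = 2.0 * kinship.values
        no_missing = obs.all()
        if no_missing:
            w = W[:, 0]
            quad = np.full(m, float(w @ K2 @ w))
            # columns can still differ in weights only through missingness;
            # with none, the quadratic form is shared
        else:
            quad = np.empty(m)
            for start in range(0, m, chunk):
                block = W[:, start:start + chunk]
                quad[start:start + chunk] = np.einsum(
                    "is,is->s", block, K2 @ block, optimize=True
                )

    var = 2.0 * p_hat * (1.0 - p_hat) * quad
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where((var > 0) & usable, D ** 2 / var, 0.0)
    stat = np.nan_to_num(stat)
    p = chi2.sf(stat, df=1)
    p = np.where((p_hat <= 0) | (p_hat >= 1) | ~usable, 1.0, p)
    stat = np.where((p_hat <= 0) | (p_hat >= 1) | ~usable, 0.0, stat)
    if single:
        return float(stat[0]), float(p[0])
    return stat, p


def association_scan(
    data: GenotypeData,
    kinship: KinshipMatrix | None = None,
    sample_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Run the corrected chi-square over every SNP of ``data``.

    Returns a table with columns snp, chrom, pos, stat, p, freq_case,
    freq_ctrl, n.  ``sample_ids`` restricts the scan (e.g. to
    misclassified subjects and their relatives); the kinship matrix is
    subset accordingly.
    """
    if sample_ids is not None:
        data = data.select_samples_by_iid(list(sample_ids))
    phen = data.samples["phenotype"].to_numpy()
    keep = np.isin(phen, (1, 2))
    if not keep.all():
        data = data.subset_samples(keep)
        phen = data.samples["phenotype"].to_numpy()
    is_case = phen == 2
    if is_case.all() or (~is_case).all():
        raise ValueError("both cases and controls are required")
    phi = kinship.subset(data.samples["iid"]) if kinship is not None else None

    d = data.dosages
    obs = d != MISSING
    dz = np.where(obs, d, 0)
    n_case_s = obs[is_case].sum(axis=0).astype(float)
    n_ctrl_s = obs[~is_case].sum(axis=0).astype(float)
    sum_case = dz[is_case].sum(axis=0, dtype=np.int64).astype(float)
    sum_ctrl = dz[~is_case].sum(axis=0, dtype=np.int64).astype(float)
    usable = (n_case_s > 0) & (n_ctrl_s > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq_case = sum_case / (2.0 * n_case_s)
        freq_ctrl = sum_ctrl / (2.0 * n_ctrl_s)
        D = freq_case * 2.0 - freq_ctrl * 2.0
        p_hat = (sum_case + sum_ctrl) / (2.0 * (n_case_s + n_ctrl_s))
        if phi is None or phi.is_unrelated:
            quad = 1.0 / n_case_s + 1.0 / n_ctrl_s
        else:
            quad = _kinship_quadratic(obs, is_case, n_case_s, n_ctrl_s, phi)
        var = 2.0 * p_hat * (1.0 - p_hat) * quad
        stat = np.where((var > 0) & usable, D ** 2 / var, 0.0)
    stat = np.nan_to_num(stat)
    degenerate = ~usable | (p_hat <= 0) | (p_hat >= 1) | ~np.isfinite(p_hat)
    stat = np.where(degenerate, 0.0, stat)
    p = np.where(degenerate, 1.0, chi2.sf(stat, df=1))
    return pd.DataFrame({
        "snp": data.snps["snp"],
        "chrom": data.snps["chrom"],
        "pos": data.snps["pos"],
        "stat": stat,
        "p": p,
        "freq_case": freq_case,
        "freq_ctrl": freq_ctrl,
        "n": obs.sum(axis=0),
    })


def _kinship_quadratic(obs, is_case, n_case_s, n_ctrl_s, phi: KinshipMatrix,
                       chunk: int = 4096) -> np.ndarray:
    """Per-SNP w'(2 Phi) w with the contrast restricted to called samples."""
    K2 = 2.0 * phi.values
    m = obs.shape[1]
    if obs.all():
        w = np.where(is_case, 1.0 / n_case_s[0], -1.0 / n_ctrl_s[0])
        return np.full(m, float(w @ K2 @ w))
    quad = np.empty(m)
    for start in range(0, m, chunk):
        sl = slice(start, start + chunk)
        W = np.where(is_case[:, None], 1.0 / n_case_s[sl], -1.0 / n_ctrl_s[sl])
        W = np.where(obs[:, sl], W, 0.0)
        quad[sl] = np.einsum("is,is->s", W, K2 @ W, optimize=True)
    return quad


def preselect(table: pd.DataFrame, mode: str, k_or_alpha) -> List[str]:
    """Pre-select SNPs from an association table.

    ``mode='top_k'`` returns the ``k`` smallest-p SNPs (ties broken by
    genomic order); ``mode='p_threshold'`` returns all SNPs with
    ``p < alpha``.  Output is in ascending-p order.
    """
    if len(table) == 0:
        raise ValueError("association table is empty")
    ranked = table.sort_values(["p", "chrom", "pos"], kind="mergesort")
    if mode == "top_k":
        k = int(k_or_alpha)
        if k > len(table):
            warnings.warn(
                f"requested top {k} of {len(table)} SNPs; returning all",
                stacklevel=2,
            )
            k = len(table)
        return list(ranked["snp"].iloc[:k])
    if mode == "p_threshold":
        alpha = float(k_or_alpha)
        if alpha >= 1.0:
            warnings.warn("p threshold >= 1 selects every SNP", stacklevel=2)
            return list(ranked["snp"])  # include p == 1 (e.g. zero statistic)
        return list(ranked.loc[ranked["p"] < alpha, "snp"])
    raise ValueError(f"unknown pre-selection mode {mode!r}")
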