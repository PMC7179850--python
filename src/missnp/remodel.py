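"""Misclassified-sample re-modeling and model mixing.

The central procedure: after a base L1-logistic model is built and
evaluated, the samples it misclassifies are treated as a putative hidden
sub-class.  SNPs are re-selected by the kinship-corrected chi-square test
restricted to those samples (plus their relatives in the full familial
cohort), a second model is fitted to them, and the two models are merged
by one of two strategies:

* ``snps_mix``  - union of the two models' *input pools*;
* ``models_mix`` - union of the two models' *selected* (nonzero) SNP sets;

followed by a LASSO refit on the original training samples and
re-evaluation on the untouched test set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .assoc import KinshipMatrix, association_scan, kinship_from_pedigree, preselect
from .genio import GenotypeData, Pedigree
from .model import (EvalReport, FittedModel, evaluate,
                    evaluate_scores, fit_lasso_cv, impute_missing,
                    split_holdout)
from .qc import QCReport, filter_phenotype, pca_ancestry_filter, select_unrelated, snp_qc
from .syndata import SimConfig, generate_cohort


class RemodelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pieces


def misclassified_samples(report: EvalReport) -> Dict[str, List[str]]:
    """Samples whose predicted label differs from the true label,
    with the breakdown by true class."""
    return {
        "ids": list(report.misclassified),
        "cases": list(report.misclassified_cases),
        "controls": list(report.misclassified_controls),
    }


def remodel_missed(
    missed_ids: Sequence[str],
    cohort: GenotypeData,
    kinship: Optional[KinshipMatrix],
    p_threshold: float = 1e-3,
    seed: int = 0,
    include_family: bool = True,
    impute_k: int = 5,
    folds: int = 10,
    n_lambda: int = 100,
    eval_mode: str = "cv",
) -> Tuple[FittedModel, List[str], EvalReport]:
    """Re-select SNPs on the misclassified samples and refit.

    Pre-selection runs the corrected chi-square restricted to the missed
    samples plus (by default) all members of their families present in
    ``cohort``, with the kinship submatrix; the model itself is fitted on
    the missed samples only.  The returned EvalReport is the stratified
    cross-validation performance on the missed set by default
    (``eval_mode='resubstitution'`` scores the training fit instead);
    either way it is optimistically biased and stamped as such.
    """
    missed_ids = [str(i) for i in missed_ids]
    if not missed_ids:
        raise RemodelError("no misclassified samples to re-model")
    samples = cohort.samples
    missed_mask = samples["iid"].isin(missed_ids).to_numpy()
    phen_missed = samples.loc[missed_mask, "phenotype"].to_numpy()
    if len(np.unique(phen_missed)) < 2:
        raise RemodelError(
            "misclassified set contains a single class; re-modeling undefined"
        )

    if include_family:
        fams = set(samples.loc[missed_mask, "fid"])
        scan_mask = samples["fid"].isin(fams).to_numpy()
    else:
        scan_mask = missed_mask
    scan_ids = list(samples.loc[scan_mask, "iid"])
    table = association_scan(cohort, kinship, sample_ids=scan_ids)
    if p_threshold >= 1:
        warnings.warn("p_threshold >= 1: pool degenerates to all SNPs", stacklevel=2)
    pool = preselect(table, "p_threshold", p_threshold)
    if not pool:
        raise RemodelError(
            f"no SNPs pass p < {p_threshold} on the misclassified set"
        )

    missed = cohort.select_samples_by_iid(missed_ids)
    cols = missed.snp_positions(pool)
    X = impute_missing(missed.dosage_float(cols), k=impute_k, snp_ids=pool)
    y = (missed.samples["phenotype"].to_numpy() == 2).astype(int)
    model = fit_lasso_cv(X, y, pool, folds=folds, n_lambda=n_lambda, seed=seed,
                         sample_ids=missed_ids)

    note = ("optimistically biased: evaluated on the same misclassified "
            f"samples the model was selected from ({eval_mode})")
    if eval_mode == "resubstitution":
        report = evaluate(model, X, y, pool, missed.samples["iid"], note=note)
    else:
        report = _cv_eval(X, y, pool, missed.samples["iid"], model.lambda_,
                          folds=folds, seed=seed, note=note)
    return model, pool, report


def _cv_eval(X, y, pool, sample_ids, lam, folds, seed, note="") -> EvalReport:
    """Out-of-fold predictions at a fixed penalty."""
    from sklearn.model_selection import StratifiedKFold
    from .model import _fit_l1
    from scipy.special import expit

    folds_eff = min(folds, int(np.bincount(y, minlength=2).min()))
    folds_eff = max(folds_eff, 2)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    scores = np.empty(len(y))
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True,
                          random_state=int(seed) % (2 ** 31))
    for tr, va in skf.split(Xs, y):
        b0, beta = _fit_l1(Xs[tr], y[tr], lam, int(seed) % (2 ** 31))
        scores[va] = expit(b0 + Xs[va] @ beta)
    return evaluate_scores(y, scores, sample_ids, note=note)


def mix_snp_pools(base_pool: Sequence[str], missed_pool: Sequence[str],
                  snps: pd.DataFrame) -> List[str]:
    """SNPs-Mix strategy: union of the two input pools, genomic order."""
    if not len(base_pool) or not len(missed_pool):
        raise RemodelError("pools must be non-empty")
    union = set(map(str, base_pool)) | set(map(str, missed_pool))
    return _genomic_order(union, snps)


def mix_model_snps(base: FittedModel, missed: FittedModel,
                   snps: Optional[pd.DataFrame] = None) -> List[str]:
    """Models-Mix strategy: union of the two selected (nonzero) SNP sets."""
    union = set(base.selected) | set(missed.selected)
    if snps is not None:
        return _genomic_order(union, snps)
    return sorted(union)


def _genomic_order(snp_set, snps: pd.DataFrame) -> List[str]:
    sub = snps[snps["snp"].isin(snp_set)]
    ordered = list(sub.sort_values(["chrom", "pos"])["snp"])
    leftover = sorted(snp_set - set(ordered))  # SNPs absent from the map
    return ordered + leftover


@dataclass
class MixReport:
    strategy: str
    base_model: FittedModel
    missed_model: FittedModel
    mixed_model: FittedModel
    input_pool: List[str]
    report: EvalReport
    base_report: EvalReport

    @property
    def delta_auc(self) -> Optional[float]:
        if self.report.auc is None or self.base_report.auc is None:
            return None
        return self.report.auc - self.base_report.auc

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "input_pool_size": len(self.input_pool),
            "model_length": self.mixed_model.length,
            "base_model_length": self.base_model.length,
            "eval": self.report.to_dict(),
            "delta_auc": self.delta_auc,
        }


def refit_and_compare(
    pool: Sequence[str],
    cohort: GenotypeData,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    base_model: FittedModel,
    missed_model: FittedModel,
    base_report: EvalReport,
    strategy: str,
    seed: int = 0,
    impute_k: int = 5,
    folds: int = 10,
    n_lambda: int = 100,
) -> MixReport:
    """Refit LASSO on the original training samples over ``pool`` and
    evaluate on the original test set."""
    pool = [str(s) for s in pool]
    X_tr, y_tr = _impute_pool(cohort, pool, list(train_ids), impute_k)
    X_te, y_te = _impute_pool(cohort, pool, list(test_ids), impute_k)
    model = fit_lasso_cv(X_tr, y_tr, pool, folds=folds,
                         n_lambda=n_lambda, seed=seed, sample_ids=train_ids)
    report = evaluate(model, X_te, y_te, pool, list(test_ids))
    return MixReport(
        strategy=strategy,
        base_model=base_model,
        missed_model=missed_model,
        mixed_model=model,
        input_pool=pool,
        report=report,
        base_report=base_report,
    )


@dataclass
class OverlapReport:
    shared: Dict[Tuple[str, str], int]
    specific: Dict[str, int]
    lengths: Dict[str, int]
    high_r2_pairs: Dict[str, List[Tuple[str, str, float]]]

    def to_dict(self) -> dict:
        return {
            "shared": {f"{a}|{b}": v for (a, b), v in sorted(self.shared.items())},
            "specific": dict(sorted(self.specific.items())),
            "lengths": dict(sorted(self.lengths.items())),
            "high_r2_pairs": {
                k: [[a, b, round(r, 6)] for a, b, r in v]
                for k, v in sorted(self.high_r2_pairs.items())
            },
        }


def model_overlap(models: Dict[str, FittedModel], genotypes: GenotypeData,
                  r2_threshold: float = 0.95) -> OverlapReport:
    """Pairwise shared-SNP counts between models, per-model specific
    counts, and within-model selected-SNP pairs with dosage r^2 above
    the threshold."""
    if len(models) < 2:
        raise RemodelError("model overlap needs at least two models")
    selected = {name: set(m.selected) for name, m in models.items()}
    names = sorted(selected)
    shared = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared[(a, b)] = len(selected[a] & selected[b])
    specific = {}
    for a in names:
        others = set().union(*(selected[b] for b in names if b != a))
        specific[a] = len(selected[a] - others)

    high_r2: Dict[str, List[Tuple[str, str, float]]] = {}
    for a in names:
        snps = _genomic_order(selected[a], genotypes.snps)
        pairs: List[Tuple[str, str, float]] = []
        if len(snps) >= 2:
            cols = genotypes.snp_positions(snps)
            df = pd.DataFrame(genotypes.dosage_float(cols), columns=snps)
            corr = df.corr().to_numpy() ** 2
            iu = np.triu_indices(len(snps), k=1)
            for r, c in zip(*iu):
                if corr[r, c] > r2_threshold:
                    pairs.append((snps[r], snps[c], float(corr[r, c])))
        high_r2[a] = pairs
    return OverlapReport(shared, specific,
                         {a: len(selected[a]) for a in names}, high_r2)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    """End-to-end configuration: simulation (or input files), QC
    thresholds, pre-selection, model building and re-modeling."""

    sim: Optional[SimConfig] = None
    input_prefix: Optional[str] = None
    pedigree_path: Optional[str] = None

    # subject QC
    pca_n_snps: int = 100_000
    pca_n_pcs: int = 2
    pc1_threshold: float = 0.0
    pca_per_group: bool = True

    # SNP QC
    min_call_rate: float = 0.98
    hwe_alpha: float = 1e-5
    hwe_on: str = "controls"

    # pre-selection
    base_pool_mode: str = "top_k"  # or "p_threshold"
    base_alpha: float = 1e-3
    base_top_k: int = 100

    # model building
    test_fraction: float = 0.2
    folds: int = 10
    n_lambda: int = 100
    impute_k: int = 5

    # re-modeling
    missed_sources: Tuple[str, ...] = ("train", "test")
    strategies: Tuple[str, ...] = ("snps_mix", "models_mix")
    remodel_p_threshold: float = 1e-3
    include_family: bool = True
    missed_eval: str = "cv"
    r2_threshold: float = 0.95

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and d["sim"] is not None and not isinstance(d["sim"], SimConfig):
            d["sim"] = SimConfig.from_dict(d["sim"])
        for key in ("missed_sources", "strategies"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    qc_report: QCReport
    association: pd.DataFrame
    pools: Dict[str, List[str]]
    base_model: FittedModel
    base_train_report: EvalReport
    base_test_report: EvalReport
    missed: Dict[str, dict]        # per source: model, pool, report, ids
    mixes: Dict[str, MixReport]    # keyed "<source>:<strategy>"
    overlap: Optional[OverlapReport]
    pc_coords: Optional[pd.DataFrame]
    seed: int
    truth: Optional["TruthManifest"] = None  # noqa: F821 - only when simulating

    def summary(self) -> dict:
        out = {
            "version": __version__,
            "seed": self.seed,
            "qc": self.qc_report.to_dict(),
            "pools": {k: len(v) for k, v in sorted(self.pools.items())},
            "base": {
                "pool_size": len(self.base_model.pool),
                "model_length": self.base_model.length,
                "lambda": self.base_model.lambda_,
                "train": self.base_train_report.to_dict(),
                "test": self.base_test_report.to_dict(),
            },
            "missed": {
                src: {
                    "n_missed": len(info["ids"]),
                    "n_missed_cases": len(info["cases"]),
                    "n_missed_controls": len(info["controls"]),
                    "pool_size": len(info["pool"]),
                    "model_length": info["model"].length,
                    "eval": info["report"].to_dict(),
                    "selection": info["selection"],
                }
                for src, info in sorted(self.missed.items())
            },
            "mixes": {k: v.to_dict() for k, v in sorted(self.mixes.items())},
            "overlap": self.overlap.to_dict() if self.overlap else None,
        }
        return out

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=1, sort_keys=True)


def _impute_pool(cohort: GenotypeData, pool: List[str], ids: List[str],
                 k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Impute the pool columns for one sample set (donors drawn only from
    within the set, so train and test never cross-contaminate)."""
    sub = cohort.select_samples_by_iid(ids)
    cols = sub.snp_positions(pool)
    X = impute_missing(sub.dosage_float(cols), k=k, snp_ids=pool)
    y = (sub.samples["phenotype"].to_numpy() == 2).astype(int)
    return X, y


def run_full_pipeline(config: PipelineConfig, seed: int = 0,
                      outdir: Optional[str] = None) -> PipelineResult:
    """Simulate (or load) -> QC -> pre-select -> base model -> re-model
    misclassified samples -> mix -> compare.  Fully determined by one
    master seed.

    The base pool is pre-selected on the full familial cohort (WADS
    analogue) *excluding the held-out test subjects*, so that in
    missed-from-train mode no test genotype or label touches any
    selection step.  Missed-from-test re-modeling necessarily feeds test
    information back (the protocol's acknowledged leak) and its outputs
    are stamped ``test-informed selection``.
    """
    ss = np.random.SeedSequence(int(seed))
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]
    (sim_seed, pca_seed, unrel_seed, split_seed,
     fit_seed, missed_seed, mix_seed, _spare) = seeds

    truth = None
    if config.sim is not None:
        cohort_bundle = generate_cohort(config.sim, seed=sim_seed)
        data, pedigree = cohort_bundle.genotypes, cohort_bundle.pedigree
        truth = cohort_bundle.truth
    elif config.input_prefix:
        from .genio import read_plink
        data = read_plink(config.input_prefix)
        pedigree = (Pedigree.read(config.pedigree_path)
                    if config.pedigree_path else Pedigree.from_samples(data.samples))
    else:
        raise RemodelError("pipeline needs either a simulation config or input files")

    # ---- subject QC
    data, qc_report = filter_phenotype(data)
    data, pc_coords, qc_report = pca_ancestry_filter(
        data, n_snps=config.pca_n_snps, n_pcs=config.pca_n_pcs,
        pc1_threshold=config.pc1_threshold, per_group=config.pca_per_group,
        seed=pca_seed, report=qc_report,
    )
    # ---- SNP QC -> WADS analogue
    wads, qc_report = snp_qc(
        data, min_call_rate=config.min_call_rate, hwe_alpha=config.hwe_alpha,
        hwe_on=config.hwe_on, report=qc_report,
    )
    # ---- one per family -> UnrADS analogue
    unrads, qc_report = select_unrelated(wads, seed=unrel_seed, report=qc_report)

    kinship = kinship_from_pedigree(pedigree).subset(wads.samples["iid"])
    if kinship.is_unrelated:
        kinship = None  # unrelated fast path

    # ---- split before pre-selection so the base pool never sees test subjects
    train_ids, test_ids = split_holdout(unrads.samples, config.test_fraction,
                                        seed=split_seed)
    test_set = set(test_ids)
    presel_ids = [i for i in wads.samples["iid"] if i not in test_set]
    table = association_scan(wads, kinship, sample_ids=presel_ids)

    pools = {
        "top_k": preselect(table, "top_k", config.base_top_k),
        "p_threshold": preselect(table, "p_threshold", config.base_alpha),
    }
    base_pool = pools[config.base_pool_mode]
    if not base_pool:
        raise RemodelError("base pre-selection produced an empty pool")

    X_tr, y_tr = _impute_pool(unrads, base_pool, train_ids, config.impute_k)
    X_te, y_te = _impute_pool(unrads, base_pool, test_ids, config.impute_k)
    base_model = fit_lasso_cv(X_tr, y_tr, base_pool,
                              folds=config.folds, n_lambda=config.n_lambda,
                              seed=fit_seed, sample_ids=train_ids)
    base_train_report = evaluate(base_model, X_tr, y_tr, base_pool, train_ids)
    base_test_report = evaluate(base_model, X_te, y_te, base_pool, test_ids)

    missed_info: Dict[str, dict] = {}
    mixes: Dict[str, MixReport] = {}
    models_for_overlap: Dict[str, FittedModel] = {"base": base_model}
    for src in config.missed_sources:
        report = base_train_report if src == "train" else base_test_report
        breakdown = misclassified_samples(report)
        if len(breakdown["ids"]) < 4:
            continue
        # restrict the re-modeling cohort to non-test families in train mode
        if src == "train":
            scan_cohort = wads.select_samples_by_iid(presel_ids)
            selection = "train-only selection"
        else:
            scan_cohort = wads
            selection = "test-informed selection"
        try:
            m_model, m_pool, m_report = remodel_missed(
                breakdown["ids"], scan_cohort, kinship,
                p_threshold=config.remodel_p_threshold, seed=missed_seed,
                include_family=config.include_family, impute_k=config.impute_k,
                folds=config.folds, n_lambda=config.n_lambda,
                eval_mode=config.missed_eval,
            )
        except RemodelError:
            continue
        missed_info[src] = dict(model=m_model, pool=m_pool, report=m_report,
                                selection=selection, **breakdown)
        models_for_overlap[f"missed_{src}"] = m_model

        strategy_pools = {
            "snps_mix": lambda: mix_snp_pools(base_pool, m_pool, wads.snps),
            "models_mix": lambda: mix_model_snps(base_model, m_model, wads.snps),
        }
        for strategy in config.strategies:
            mixed_pool = strategy_pools[strategy]()
            if not mixed_pool:
                continue
            mix = refit_and_compare(
                mixed_pool, unrads, train_ids, test_ids, base_model, m_model,
                base_test_report, strategy, seed=mix_seed,
                impute_k=config.impute_k, folds=config.folds,
                n_lambda=config.n_lambda,
            )
            key = f"{src}:{strategy}"
            mixes[key] = mix
            models_for_overlap[key] = mix.mixed_model

    overlap = (model_overlap(models_for_overlap, unrads,
                             r2_threshold=config.r2_threshold)
               if len(models_for_overlap) >= 2 else None)

    result = PipelineResult(
        qc_report=qc_report, association=table, pools=pools,
        base_model=base_model, base_train_report=base_train_report,
        base_test_report=base_test_report, missed=missed_info, mixes=mixes,
        overlap=overlap, pc_coords=pc_coords, seed=int(seed), truth=truth,
    )
    if outdir:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: str) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(result.summary_json())
    result.association.to_csv(out / "association.tsv", sep="\t", index=False)
    with open(out / "base_model.json", "w") as fh:
        json.dump(result.base_model.to_dict(), fh, indent=1, sort_keys=True)
    for src, info in result.missed.items():
        with open(out / f"missed_{src}_model.json", "w") as fh:
            json.dump(info["model"].to_dict(), fh, indent=1, sort_keys=True)
    for key, mix in result.mixes.items():
        name = key.replace(":", "_")
        with open(out / f"mix_{name}_model.json", "w") as fh:
            json.dump(mix.mixed_model.to_dict(), fh, indent=1, sort_keys=True)
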