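"""L1-regularized logistic model building and evaluation.

The protocol: k-nearest-neighbour median imputation of missing dosages, a
seeded stratified 80/20 holdout, a penalty path tuned by the minimum mean
binomial deviance over stratified 10-fold cross-validation, a refit on the
full training set at the tuned penalty, and evaluation (confusion matrix,
accuracy, sensitivity, specificity, trapezoidal ROC AUC) on the blind
test set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.metrics.pairwise import nan_euclidean_distances
from sklearn.model_selection import StratifiedKFold, train_test_split


class ModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# imputation


def impute_missing(matrix: np.ndarray, k: int = 5,
                   snp_ids: Optional[Sequence[str]] = None) -> np.ndarray:
    """k-nearest-neighbour median imputation of missing dosages.

    For each missing cell, the ``k`` nearest samples (Euclidean distance
    over mutually non-missing SNPs, scaled for the masked coordinates)
    that are called at that SNP donate their values; the cell receives
    their median, rounded to the nearest value in {0, 1, 2} (half to
    even).  A matrix without missing cells is returned unchanged (copy).
    """
    X = np.asarray(matrix, dtype=float).copy()
    X[X == -1] = np.nan
    nan_mask = np.isnan(X)
    if not nan_mask.any():
        return X
    fully_missing = nan_mask.all(axis=0)
    if fully_missing.any():
        j = int(np.flatnonzero(fully_missing)[0])
        name = snp_ids[j] if snp_ids is not None else f"column {j}"
        raise ModelError(f"SNP {name} has no observed calls; cannot impute")

    dist = nan_euclidean_distances(X, X)
    np.fill_diagonal(dist, np.inf)
    rows_with_missing = np.flatnonzero(nan_mask.any(axis=1))
    for i in rows_with_missing:
        order = np.argsort(dist[i], kind="stable")
        for j in np.flatnonzero(nan_mask[i]):
            donors = order[~nan_mask[order, j]][:k]
            med = np.median(X[donors, j])
            X[i, j] = min(2.0, max(0.0, np.rint(med)))
    return X


# ---------------------------------------------------------------------------
# split


def split_holdout(samples: pd.DataFrame, test_fraction: float = 0.2,
                  seed: int = 0) -> Tuple[List[str], List[str]]:
    """Stratified train/test partition of sample IDs by phenotype."""
    if not (0 < test_fraction < 1):
        raise ModelError(f"test_fraction must be in (0, 1), got {test_fraction}")
    phen = samples["phenotype"].to_numpy()
    if min((phen == 2).sum(), (phen == 1).sum()) < 2:
        raise ModelError("both classes need at least two members for a stratified split")
    ids = samples["iid"].to_numpy()
    train, test = train_test_split(
        ids, test_size=test_fraction, stratify=phen, random_state=int(seed) % (2 ** 31)
    )
    return list(train), list(test)


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class FittedModel:
    """L1-logistic model over a SNP pool.

    Coefficients are stored on the raw dosage scale (the standardized-
    scale coefficients from the fit are also kept); prediction is
    ``logistic(intercept + sum coef * dosage)`` on imputed dosages.
    """

    intercept: float
    coefficients: Dict[str, float]        # raw-dosage scale, pool order
    coefficients_std: Dict[str, float]    # standardized scale
    lambda_: float
    pool: List[str]
    train_means: Dict[str, float]
    train_scales: Dict[str, float]
    train_fingerprint: str
    seed: int
    cv_deviance: Optional[pd.DataFrame] = None

    @property
    def selected(self) -> List[str]:
        return [s for s in self.pool if self.coefficients_std[s] != 0.0]

    @property
    def length(self) -> int:
        return len(self.selected)

    def predict_proba(self, X: np.ndarray, snp_ids: Sequence[str]) -> np.ndarray:
        idx = pd.Index(snp_ids).get_indexer(self.pool)
        if (idx < 0).any():
            missing = [s for s, i in zip(self.pool, idx) if i < 0]
            raise ModelError(f"model SNPs absent from data: {missing[:5]}")
        beta = np.array([self.coefficients[s] for s in self.pool])
        eta = self.intercept + np.asarray(X, dtype=float)[:, idx] @ beta
        return expit(eta)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "lambda": self.lambda_,
            "pool": self.pool,
            "selected": self.selected,
            "seed": self.seed,
            "train_fingerprint": self.train_fingerprint,
        }


def _fingerprint(sample_ids: Sequence[str], seed: int) -> str:
    h = hashlib.sha256()
    h.update(("\n".join(sorted(map(str, sample_ids))) + f"|{seed}").encode())
    return h.hexdigest()[:16]


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_l1(Xs: np.ndarray, y: np.ndarray, lam: float, seed: int,
            tol: float = 1e-7) -> Tuple[float, np.ndarray]:
    """One L1-logistic fit at glmnet-style penalty ``lam`` (mean-loss scale)."""
    n = len(y)
    C = 1.0 / max(n * lam, 1e-12)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=tol, max_iter=2000,
        random_state=seed, fit_intercept=True,
    )
    clf.fit(Xs, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def fit_lasso_cv(
    X: np.ndarray,
    y: np.ndarray,
    snp_ids: Sequence[str],
    folds: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
    lambda_min_ratio: float = 1e-4,
    sample_ids: Optional[Sequence[str]] = None,
    patience: Optional[int] = 15,
) -> FittedModel:
    """Tune the L1 penalty by stratified CV and refit on the full set.

    ``X`` is the imputed dosage matrix restricted to the SNP pool, ``y``
    the binary labels (1 = case).  Dosages are standardized to zero mean
    and unit variance on the training set; the penalty grid is log-spaced
    from the smallest value that zeroes every coefficient down four
    decades (``lambda_min_ratio``); the penalty minimizing the mean
    cross-validated binomial deviance is selected (ties go to the
    stronger penalty).  Folds auto-reduce to the smallest class size.

    The path is walked from the strongest penalty downward and abandoned
    once ``patience`` consecutive grid points fail to improve the best
    mean deviance (the curve is convex-ish in practice, so weaker
    penalties past that point only overfit further); ``patience=None``
    evaluates the full grid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ModelError("training matrix must be imputed before fitting")
    snp_ids = [str(s) for s in snp_ids]
    n, m = X.shape
    if m != len(snp_ids):
        raise ModelError("snp_ids length does not match matrix width")
    class_counts = np.bincount(y, minlength=2)
    folds_eff = min(folds, int(class_counts.min()))
    if folds_eff < 2:
        raise ModelError("each class needs at least two members for CV")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    ybar = y.mean()
    lambda_max = float(np.abs(Xs.T @ (y - ybar)).max() / n)
    if lambda_max <= 0:
        lambda_max = 1e-3
    grid = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambda)

    seed = int(seed) % (2 ** 31)
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    splits = list(skf.split(Xs, y))
    dev = np.zeros((folds_eff, n_lambda))
    n_evaluated = n_lambda
    best = 0
    since_best = 0
    for li, lam in enumerate(grid):
        for f, (tr, va) in enumerate(splits):
            b0, beta = _fit_l1(Xs[tr], y[tr], lam, seed, tol=1e-5)
            p = expit(b0 + Xs[va] @ beta)
            dev[f, li] = _deviance(y[va], p)
        if dev[:, li].mean() < dev[:, best].mean():  # strict: ties keep larger lambda
            best, since_best = li, 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                n_evaluated = li + 1
                break
    grid = grid[:n_evaluated]
    mean_dev = dev[:, :n_evaluated].mean(axis=0)
    lam = float(grid[best])

    b0, beta_std = _fit_l1(Xs, y, lam, seed)
    beta_raw = beta_std / sd
    intercept = float(b0 - np.sum(beta_std * mu / sd))
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    return FittedModel(
        intercept=intercept,
        coefficients={s: float(b) for s, b in zip(snp_ids, beta_raw)},
        coefficients_std={s: float(b) for s, b in zip(snp_ids, beta_std)},
        lambda_=lam,
        pool=list(snp_ids),
        train_means={s: float(v) for s, v in zip(snp_ids, mu)},
        train_scales={s: float(v) for s, v in zip(snp_ids, sd)},
        train_fingerprint=_fingerprint(ids, seed),
        seed=seed,
        cv_deviance=pd.DataFrame({"lambda": grid, "mean_deviance": mean_dev}),
    )


# ---------------------------------------------------------------------------
# evaluation


def auc_score(y: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal area under the exact ROC curve (ties handled by the
    rank / Mann-Whitney formulation); equals U / (n_case * n_ctrl)."""
    fpr, tpr, _ = roc_curve(y, scores)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class EvalReport:
    """Confusion matrix (case = positive), scalar metrics and the identity
    of misclassified samples split by true class."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: Optional[float]
    scores: pd.Series = field(repr=False, default=None)
    misclassified_cases: List[str] = field(default_factory=list)
    misclassified_controls: List[str] = field(default_factory=list)
    note: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def misclassified(self) -> List[str]:
        return self.misclassified_cases + self.misclassified_controls

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n": self.n,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n_misclassified_cases": len(self.misclassified_cases),
            "n_misclassified_controls": len(self.misclassified_controls),
            "note": self.note,
        }


def evaluate_scores(y: np.ndarray, scores: np.ndarray,
                    sample_ids: Sequence[str], threshold: float = 0.5,
                    note: str = "") -> EvalReport:
    """Build an :class:`EvalReport` from case probabilities.

    Predicted label is case iff score >= threshold.  With a single-class
    evaluation set the AUC is undefined and reported as None.
    """
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    ids = np.asarray([str(s) for s in sample_ids])
    pred = scores >= threshold
    actual = y == 1
    tp = int((pred & actual).sum())
    fp = int((pred & ~actual).sum())
    tn = int((~pred & ~actual).sum())
    fn = int((~pred & actual).sum())
    n = len(y)
    acc = (tp + tn) / n if n else float("nan")
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    auc = auc_score(y, scores) if 0 < actual.sum() < n else None
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=acc, sensitivity=sens, specificity=spec, auc=auc,
        scores=pd.Series(scores, index=ids),
        misclassified_cases=list(ids[actual & ~pred]),
        misclassified_controls=list(ids[~actual & pred]),
        note=note,
    )


def evaluate(model: FittedModel, X: np.ndarray, y: np.ndarray,
             snp_ids: Sequence[str], sample_ids: Sequence[str],
             threshold: float = 0.5, note: str = "") -> EvalReport:
    """Score an imputed dosage matrix with ``model`` and report metrics."""
    scores = model.predict_proba(X, snp_ids)
    return evaluate_scores(y, scores, sample_ids, threshold=threshold, note=note)
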