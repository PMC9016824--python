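"""Classifier training/validation and group statistics.

The evaluation harness mirrors the standard biomarker workflow: stratified
10-fold cross-validation of a logistic-regression classifier on one measure,
ROC analysis of the pooled out-of-fold scores (Mann-Whitney AUC with ties
counted 1/2, Youden-J optimal threshold), and the accompanying statistics -
Cohen's d effect size, the Kruskal-Wallis rank test, and Pearson
correlations against clinical scores (MMSE, CDR-SOB).

Labels are coded HC = 0, AD = 1 throughout, and higher scores mean "more
AD-like".  The logistic fit carries a small L2 ridge stabilizer (default
1e-6) so that perfectly separated data - which a strongly discriminating
measure produces routinely - still yields finite weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "ConvergenceError",
    "ClassifierModel",
    "RocResult",
    "CrossValResult",
    "EvaluationReport",
    "stratified_folds",
    "fit_logistic",
    "crossvalidate",
    "roc_analysis",
    "cohens_d",
    "kruskal_wallis",
    "pearson_corr",
    "evaluate_measure",
    "threshold_metrics",
]


class ConvergenceError(RuntimeError):
    """Raised when the logistic fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, n_iter: int, grad_norm: float) -> None:
        super().__init__(f"{message} (iterations={n_iter}, |grad|={grad_norm:.3g})")
        self.n_iter = n_iter
        self.grad_norm = grad_norm


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":  # group names
        y = (y == "AD").astype(float)
    else:
        y = y.astype(float)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("labels must be binary 0/1 (or 'HC'/'AD' strings)")
    return y


def stratified_folds(labels, k: int, rng=None) -> np.ndarray:
    """Assign each subject to one of ``k`` folds, stratified by class.

    Within each class, subjects are shuffled and dealt round-robin, so
    per-fold class counts differ by at most 1 from perfect stratification
    (e.g. 50 + 50 subjects in 10 folds gives exactly 5 + 5 per fold).
    Deterministic for a fixed seed.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("need at least 2 folds")
    gen = _rng(rng)
    folds = np.full(y.shape[0], -1, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} subjects, fewer than k={k} folds"
            )
        gen.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted logistic model: score(x) = sigmoid(intercept + x . weights)."""

    weights: np.ndarray
    intercept: float
    se: np.ndarray  # standard errors, intercept first
    n_iter: int
    converged: bool
    ridge: float

    def decision(self, x) -> np.ndarray:
        X = np.atleast_2d(np.asarray(x, dtype=float).T).T
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept + X @ self.weights

    def predict_proba(self, x) -> np.ndarray:
        return expit(self.decision(x))


def _design(x) -> np.ndarray:
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def fit_logistic(
    x,
    y,
    ridge: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ClassifierModel:
    """Ridge-stabilized logistic regression by Newton/IRLS with line search.

    Maximizes  sum_i [y_i eta_i - log(1 + e^{eta_i})] - ridge/2 * ||w||^2
    (intercept unpenalized).  Convergence: max|gradient| < tol or step
    max-norm < tol within ``max_iter`` iterations; otherwise raises
    :class:`ConvergenceError` with iteration diagnostics.  With ridge > 0
    the optimum is finite even for perfectly separated data.
    """
    X = _design(x)
    yb = _binary_labels(y)
    if np.unique(yb).size < 2:
        raise ValueError("both classes must be present to fit a classifier")
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    pen = np.concatenate(([0.0], np.full(p, ridge)))  # intercept unpenalized
    beta = np.zeros(p + 1)

    def objective(b: np.ndarray) -> float:
        eta = Xd @ b
        ll = float(np.sum(yb * eta - np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(np.sum(pen * b * b))

    obj = objective(beta)
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = expit(eta)
        grad = Xd.T @ (yb - mu) - pen * beta
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            se = _logistic_se(Xd, mu, pen)
            return ClassifierModel(beta[1:].copy(), float(beta[0]), se, it, True, ridge)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton: halve until the penalized log-likelihood improves
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        moved = float(np.max(np.abs(t * step)))
        new_obj = objective(beta)
        if moved < tol and new_obj <= obj + abs(obj) * 1e-12 + 1e-12:
            mu = expit(Xd @ beta)
            se = _logistic_se(Xd, mu, pen)
            return ClassifierModel(beta[1:].copy(), float(beta[0]), se, it, True, ridge)
        obj = new_obj
    raise ConvergenceError("logistic regression did not converge", max_iter, grad_norm)


def _logistic_se(Xd: np.ndarray, mu: np.ndarray, pen: np.ndarray) -> np.ndarray:
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (Xd * w[:, None]).T @ Xd + np.diag(pen)
    try:
        cov = np.linalg.inv(H)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(Xd.shape[1], np.nan)


@dataclass(frozen=True)
class RocResult:
    """ROC analysis of scores against binary labels."""

    auc: float
    thresholds: np.ndarray  # descending distinct score values
    tpr: np.ndarray
    fpr: np.ndarray
    optimal_threshold: float  # maximizes Youden's J, ties -> higher specificity
    sensitivity: float
    specificity: float
    accuracy: float


def roc_analysis(scores, labels) -> RocResult:
    """ROC curve, Mann-Whitney AUC, and Youden-optimal operating point.

    AUC is the probability that a random AD score exceeds a random HC score,
    with ties counted 1/2 (rank formulation).  The curve sweeps every
    distinct score as a threshold (predict AD when score >= threshold); the
    optimal threshold maximizes J = sensitivity + specificity - 1, with ties
    broken toward higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    if np.any(np.isnan(s)):
        raise ValueError("scores must not contain NaN")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(s)
    auc = float((np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2.0) / (n1 * n0))

    thr = np.unique(s)[::-1]
    sp = np.sort(s[y == 1])
    sn = np.sort(s[y == 0])
    tp = n1 - np.searchsorted(sp, thr, side="left")
    fp = n0 - np.searchsorted(sn, thr, side="left")
    tpr = tp / n1
    fpr = fp / n0
    j = tpr - fpr
    # thresholds descend, so fpr is non-decreasing along the array: the first
    # index attaining max J has the highest specificity among ties
    best = int(np.argmax(j))
    sens = float(tpr[best])
    spec = float(1.0 - fpr[best])
    acc = float((tp[best] + (n0 - fp[best])) / (n1 + n0))
    return RocResult(
        auc=auc,
        thresholds=thr,
        tpr=tpr,
        fpr=fpr,
        optimal_threshold=float(thr[best]),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
    )


@dataclass(frozen=True)
class CrossValResult:
    """Pooled out-of-fold scores of a stratified CV run plus ROC analysis."""

    oof_scores: np.ndarray
    folds: np.ndarray
    roc: RocResult
    models: Tuple[ClassifierModel, ...]
    measure_threshold: Optional[float]  # optimal threshold on the measure scale

    @property
    def accuracy(self) -> float:
        return self.roc.accuracy

    @property
    def auc(self) -> float:
        return self.roc.auc


def crossvalidate(
    measure,
    labels,
    k: int = 10,
    rng=None,
    folds: Optional[np.ndarray] = None,
    ridge: float = 1e-6,
) -> CrossValResult:
    """Stratified k-fold CV of a logistic classifier on one measure.

    Trains on k-1 folds, scores the held-out fold, pools all out-of-fold
    probability scores, and runs :func:`roc_analysis` on them against the
    true labels.  For a single measure the score is a monotone transform of
    it within each fold, so the optimal probability threshold is also mapped
    back to the measure scale (median of the per-fold inverse logits).
    """
    X = _design(measure)
    y = _binary_labels(labels)
    if folds is None:
        folds = stratified_folds(y, k, rng)
    else:
        folds = np.asarray(folds, dtype=int)
        k = int(folds.max()) + 1
    oof = np.empty(y.shape[0])
    models: List[ClassifierModel] = []
    for f in range(k):
        test = folds == f
        if not np.any(test):
            continue
        model = fit_logistic(X[~test], y[~test], ridge=ridge)
        oof[test] = model.predict_proba(X[test])
        models.append(model)
    roc = roc_analysis(oof, y)
    measure_threshold: Optional[float] = None
    if X.shape[1] == 1:
        s_star = float(np.clip(roc.optimal_threshold, 1e-12, 1 - 1e-12))
        inv = [
            (logit(s_star) - m.intercept) / m.weights[0]
            for m in models
            if m.weights[0] != 0
        ]
        if inv:
            measure_threshold = float(np.median(inv))
    return CrossValResult(
        oof_scores=oof,
        folds=folds,
        roc=roc,
        models=tuple(models),
        measure_threshold=measure_threshold,
    )


def cohens_d(x_ad, x_hc) -> float:
    """Cohen's d, (mean_AD - mean_HC) / pooled sd (AD-minus-HC convention)."""
    a = np.asarray(x_ad, dtype=float)
    h = np.asarray(x_hc, dtype=float)
    if a.size < 2 or h.size < 2:
        raise ValueError("need at least 2 values per group")
    n1, n2 = a.size, h.size
    pooled = math.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * h.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - h.mean()) / pooled)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from the chi-square approximation.

    All-identical values across groups return (0.0, 1.0) rather than erroring
    (the tie-correction denominator vanishes there).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def pearson_corr(x, y) -> Tuple[float, float]:
    """Pearson r and its t-distribution p-value; NaN pairs dropped pairwise."""
    xa = np.asarray(
        [np.nan if v is None else float(v) for v in np.asarray(x, dtype=object)]
    )
    ya = np.asarray(
        [np.nan if v is None else float(v) for v in np.asarray(y, dtype=object)]
    )
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


@dataclass
class EvaluationReport:
    """ROC metrics, effect size, rank test, and clinical correlations for one
    measure (the table-shaped summary of the evaluation stage)."""

    measure: str
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    optimal_threshold: Optional[float]  # on the measure scale when available
    threshold_score: Optional[float] = None  # on the probability-score scale
    effect_size: Optional[float] = None
    kw_statistic: Optional[float] = None
    kw_p: Optional[float] = None
    corr_mmse: Optional[Tuple[float, float]] = None
    corr_cdr_sob: Optional[Tuple[float, float]] = None
    folds: Optional[List[int]] = None

    def to_dict(self) -> Dict:
        opt = lambda v: None if v is None else float(v)  # noqa: E731
        pair = lambda v: None if v is None else [float(v[0]), float(v[1])]  # noqa: E731
        return {
            "measure": self.measure,
            "auc": float(self.auc),
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "accuracy": float(self.accuracy),
            "optimal_threshold": opt(self.optimal_threshold),
            "threshold_score": opt(self.threshold_score),
            "effect_size": opt(self.effect_size),
            "kw_statistic": opt(self.kw_statistic),
            "kw_p": opt(self.kw_p),
            "corr_mmse": pair(self.corr_mmse),
            "corr_cdr_sob": pair(self.corr_cdr_sob),
            "folds": None if self.folds is None else [int(f) for f in self.folds],
        }


def evaluate_measure(
    values,
    labels,
    k: int = 10,
    rng=None,
    mmse=None,
    cdr_sob=None,
    measure_name: str = "",
    ridge: float = 1e-6,
) -> EvaluationReport:
    """Full single-measure evaluation: CV ROC + effect size + rank test +
    optional clinical-score correlations."""
    v = np.asarray(values, dtype=float)
    y = _binary_labels(labels)
    cv = crossvalidate(v, y, k=k, rng=rng, ridge=ridge)
    d = cohens_d(v[y == 1], v[y == 0])
    h, p = kruskal_wallis([v[y == 1], v[y == 0]])
    report = EvaluationReport(
        measure=measure_name,
        auc=cv.roc.auc,
        sensitivity=cv.roc.sensitivity,
        specificity=cv.roc.specificity,
        accuracy=cv.roc.accuracy,
        optimal_threshold=cv.measure_threshold,
        threshold_score=cv.roc.optimal_threshold,
        effect_size=d,
        kw_statistic=h,
        kw_p=p,
        folds=list(cv.folds),
    )
    if mmse is not None:
        report.corr_mmse = pearson_corr(v, mmse)
    if cdr_sob is not None:
        report.corr_cdr_sob = pearson_corr(v, cdr_sob)
    return report


def threshold_metrics(values, labels, threshold: float) -> EvaluationReport:
    """Evaluate a measure on held-out subjects with a fixed (training-derived)
    measure-scale threshold: predict AD when value >= threshold."""
    v = np.asarray(values, dtype=float)
    y = _binary_labels(labels)
    pred = (v >= threshold).astype(float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    sens = float(np.sum(pred[y == 1] == 1) / n1)
    spec = float(np.sum(pred[y == 0] == 0) / n0)
    acc = float((sens * n1 + spec * n0) / (n1 + n0))
    auc = roc_analysis(v, y).auc  # threshold-free ranking quality
    return EvaluationReport(
        measure="",
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        optimal_threshold=threshold,
    )
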