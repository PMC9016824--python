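"""Parameter optimization and region selection for the two-slope index.

Two fitting procedures live here:

* :func:`optimize_params` - exhaustive grid search over (a, t1, t2).  For
  every grid point the index is computed for all subjects in one region and
  scored by stratified cross-validated logistic-regression classification
  accuracy; the maximizing parameters are returned with ties broken toward
  the minimal required scan time max(t1, t2), then minimal t1, then minimal
  a, so the cheapest acquisition wins among equally accurate settings.

* :func:`lasso_select` - lasso regression of the binary group label on the
  per-region index matrix (standardized internally), with the regularization
  strength chosen by the cross-validated one-standard-error rule; regions
  with nonzero coefficients are the "featured" regions.  The selected
  regions are then combined into a single composite index by ordinary least
  squares on z-scored features (:func:`fit_overall` / :func:`apply_overall`),
  AQI_overall = sum_j beta_j X_j + intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from . import evaluate
from .frames import SubjectRecord
from .quantify import AQIParams, aqi_value

__all__ = [
    "GridSpec",
    "GridResult",
    "LassoSelection",
    "OverallIndexModel",
    "optimize_params",
    "lasso_select",
    "fit_overall",
    "apply_overall",
    "aqi_feature_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Search grid for (a, t1, t2), seconds for the time axes.

    Defaults: t1 in [50, 3300] step 50 s, t2 in [300, 3300] step 50 s, and
    a in [0, 1] step 0.1.  (t1 starts at 50 s rather than 0: the retention
    slope divides by t1, so t1 = 0 is undefined.)
    """

    t1_range: Tuple[float, float] = (50.0, 3300.0)
    t1_step: float = 50.0
    t2_range: Tuple[float, float] = (300.0, 3300.0)
    t2_step: float = 50.0
    a_range: Tuple[float, float] = (0.0, 1.0)
    a_step: float = 0.1

    def __post_init__(self) -> None:
        for step in (self.t1_step, self.t2_step, self.a_step):
            if step <= 0:
                raise ValueError("grid steps must be positive")
        if self.t1_range[0] <= 0:
            raise ValueError("t1 grid must start above 0 (the index divides by t1)")

    @staticmethod
    def _axis(lo: float, hi: float, step: float) -> np.ndarray:
        n = int(round((hi - lo) / step))
        return np.round(lo + step * np.arange(n + 1), 10)

    @property
    def t1_values(self) -> np.ndarray:
        return self._axis(*self.t1_range, self.t1_step)

    @property
    def t2_values(self) -> np.ndarray:
        return self._axis(*self.t2_range, self.t2_step)

    @property
    def a_values(self) -> np.ndarray:
        return self._axis(*self.a_range, self.a_step)


@dataclass(frozen=True)
class GridResult:
    """Grid-search outcome: best parameters and the full accuracy surface."""

    best_params: AQIParams
    best_accuracy: float
    surface: pd.DataFrame  # columns t1, t2, a, accuracy, valid


def optimize_params(
    cohort: Sequence[SubjectRecord],
    region: str,
    grid: GridSpec = GridSpec(),
    cv_folds: int = 10,
    rng=None,
) -> GridResult:
    """Grid-search (a, t1, t2) maximizing cross-validated accuracy.

    For each grid point the single-region index is computed for every
    subject and scored by :func:`aqipet.evaluate.crossvalidate` (accuracy at
    the Youden-optimal threshold of the pooled out-of-fold scores).  One
    fold assignment, drawn once from ``rng``, is reused across the whole
    grid so the search is deterministic for a fixed seed.  Grid points where
    any subject violates t2 > t_max, or where t1/t2 exceed a subject's
    scanned range, are excluded (scored NaN) rather than failing the search.
    """
    labels = np.array([s.group for s in cohort])
    if not (np.any(labels == "AD") and np.any(labels == "HC")):
        raise ValueError("cohort must contain both AD and HC subjects")
    y = (labels == "AD").astype(float)

    tacs = []
    for s in cohort:
        if region not in s.tacs:
            raise ValueError(f"subject {s.subject_id}: region {region!r} missing")
        tacs.append(s.tacs[region])

    mids_last = np.array([t.schedule.mid_times[-1] for t in tacs])
    s0 = np.array([t.activity[0] for t in tacs])
    tmax = np.array([t.tmax() for t in tacs])
    smax = np.array([t.interpolate(tm) for t, tm in zip(tacs, tmax)])
    dose = np.array([t.injected_dose for t in tacs])
    max_tmax = float(tmax.max())
    min_last = float(mids_last.min())

    t1s, t2s, avals = grid.t1_values, grid.t2_values, grid.a_values
    times = np.unique(np.concatenate([t1s, t2s]))
    # S(t) for every subject at every grid time (t <= each subject's range)
    S = np.empty((len(tacs), times.size))
    for i, t in enumerate(tacs):
        ok = times <= mids_last[i] + 1e-9
        S[i, ok] = t.interpolate(times[ok])
        S[i, ~ok] = np.nan
    t_index = {t: j for j, t in enumerate(times)}

    folds = evaluate.stratified_folds(y, cv_folds, rng)

    rows: List[tuple] = []
    best_key: Optional[tuple] = None
    best: Optional[tuple] = None
    n_invalid = 0
    for t1 in t1s:
        i1 = t_index[t1]
        slope1 = (S[:, i1] - s0) / t1  # may be NaN where t1 out of range
        for t2 in t2s:
            i2 = t_index[t2]
            if t2 > min_last + 1e-9 or t2 <= max_tmax or t1 > min_last + 1e-9:
                rows.extend((t1, t2, a, np.nan, False) for a in avals)
                n_invalid += len(avals)
                continue
            slope2 = (smax - S[:, i2]) / (t2 - tmax)
            for a in avals:
                feature = (a * slope1 - (1.0 - a) * slope2) / dose
                cv = evaluate.crossvalidate(feature, y, folds=folds)
                acc = cv.accuracy
                rows.append((t1, t2, a, acc, True))
                key = (-acc, max(t1, t2), t1, a)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, t1, t2, acc)
    if best is None:
        raise ValueError("no valid grid point (t2 never exceeded every t_max)")
    if n_invalid:
        logger.info("grid search: %d invalid grid points excluded", n_invalid)
    a_b, t1_b, t2_b, acc_b = best
    surface = pd.DataFrame(rows, columns=["t1", "t2", "a", "accuracy", "valid"])
    return GridResult(
        best_params=AQIParams(a=float(a_b), t1=float(t1_b), t2=float(t2_b)),
        best_accuracy=float(acc_b),
        surface=surface,
    )


# ---------------------------------------------------------------------------
# lasso region selection


@dataclass(frozen=True)
class LassoSelection:
    """Outcome of one-standard-error lasso selection."""

    regions: Tuple[str, ...]  # sorted by |beta| descending
    beta: Dict[str, float]  # nonzero coefficients (standardized scale)
    alpha: float  # regularization strength chosen by the 1-SE rule
    alphas: np.ndarray  # full path, descending
    coef_path: pd.DataFrame  # regions x alphas coefficients on the full data
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray


def lasso_select(
    features: pd.DataFrame,
    labels,
    lambda_grid: Optional[np.ndarray] = None,
    cv_folds: int = 10,
    rng=None,
    coef_floor: float = 1e-6,
) -> LassoSelection:
    """Select featured regions by lasso with the cross-validated 1-SE rule.

    The binary group label (HC = 0, AD = 1) is regressed on the standardized
    per-region index matrix over a descending path of regularization
    strengths.  Stratified ``cv_folds``-fold CV estimates the mean squared
    prediction error per strength; the chosen strength is the largest one
    whose mean MSE lies within one standard error of the minimum.  Regions
    whose refitted coefficient magnitude exceeds ``coef_floor`` are returned,
    sorted by |beta| descending.  A constant response selects nothing; a
    constant feature column is dropped with a warning.
    """
    X_df = features.copy()
    y = evaluate._binary_labels(labels)
    if np.unique(y).size < 2:
        return LassoSelection(
            regions=(),
            beta={},
            alpha=float("inf"),
            alphas=np.array([]),
            coef_path=pd.DataFrame(index=list(X_df.columns)),
            cv_mse_mean=np.array([]),
            cv_mse_se=np.array([]),
        )
    sds = X_df.std(axis=0, ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        logger.warning("dropping constant feature column(s): %s", constant)
        X_df = X_df.drop(columns=constant)
    if X_df.shape[1] == 0:
        raise ValueError("no non-constant feature columns remain")
    names = list(X_df.columns)
    X = (X_df.to_numpy(dtype=float) - X_df.mean(axis=0).to_numpy()) / sds[
        names
    ].to_numpy()
    n = X.shape[0]

    if lambda_grid is None:
        alpha_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / n)
        lambda_grid = np.geomspace(alpha_max, alpha_max * 1e-4, 100)
    alphas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    folds = evaluate.stratified_folds(y, cv_folds, rng)
    mse = np.empty((cv_folds, alphas.size))
    for f in range(cv_folds):
        test = folds == f
        Xtr, ytr = X[~test], y[~test]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        _, coefs, _ = lasso_path(Xtr - xm, ytr - ym, alphas=alphas)
        pred = (X[test] - xm) @ coefs + ym  # n_test x n_alphas
        mse[f] = np.mean((pred - y[test, None]) ** 2, axis=0)
    mean = mse.mean(axis=0)
    se = mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(mean))
    within = np.flatnonzero(mean <= mean[i_min] + se[i_min])
    i_1se = int(within[0])  # alphas descend: first qualifying index = largest

    _, full_coefs, _ = lasso_path(
        X - X.mean(axis=0), y - y.mean(), alphas=alphas
    )
    refit = Lasso(alpha=float(alphas[i_1se]), fit_intercept=True, max_iter=50_000)
    refit.fit(X, y)
    beta = {
        name: float(c)
        for name, c in zip(names, refit.coef_)
        if abs(c) > coef_floor
    }
    order = sorted(beta, key=lambda r: abs(beta[r]), reverse=True)
    return LassoSelection(
        regions=tuple(order),
        beta=beta,
        alpha=float(alphas[i_1se]),
        alphas=alphas,
        coef_path=pd.DataFrame(full_coefs, index=names, columns=alphas),
        cv_mse_mean=mean,
        cv_mse_se=se,
    )


# ---------------------------------------------------------------------------
# composite index


@dataclass(frozen=True)
class OverallIndexModel:
    """Linear composite of z-scored per-region indices.

    AQI_overall = sum_j coef_j * z_j + intercept, where z_j uses the stored
    training means/sds - new subjects are normalized with the training
    statistics, never their own.
    """

    regions: Tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    coef: np.ndarray
    intercept: float

    def to_dict(self) -> Dict:
        return {
            "regions": list(self.regions),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "OverallIndexModel":
        return cls(
            regions=tuple(d["regions"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
        )


def fit_overall(features: pd.DataFrame, labels) -> OverallIndexModel:
    """OLS of the 0/1 group label on z-scored selected-region features.

    With centered predictors the intercept equals the label mean, i.e. 0.5
    exactly on a balanced cohort.  Zero-variance features cannot be z-scored
    and raise.
    """
    y = evaluate._binary_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("both groups must be present")
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [n for n, s in zip(names, sds) if s == 0]
        raise ValueError(f"zero-variance feature(s), cannot z-score: {bad}")
    Z = (X - means) / sds
    design = np.column_stack([np.ones(len(y)), Z])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return OverallIndexModel(
        regions=tuple(names),
        means=means,
        sds=sds,
        coef=coef[1:],
        intercept=float(coef[0]),
    )


def apply_overall(model: OverallIndexModel, features) -> np.ndarray:
    """Composite index for new subjects using the stored training z-scoring.

    ``features`` is a DataFrame (or mapping of region -> values) that must
    cover every region of the model; a missing region raises, naming it.
    """
    if isinstance(features, pd.DataFrame):
        cols = features.columns
        getter = lambda r: features[r].to_numpy(dtype=float)  # noqa: E731
    else:
        cols = features.keys()
        getter = lambda r: np.asarray(features[r], dtype=float)  # noqa: E731
    missing = [r for r in model.regions if r not in cols]
    if missing:
        raise ValueError(f"missing region value(s): {missing}")
    Z = np.column_stack(
        [
            (getter(r) - m) / s
            for r, m, s in zip(model.regions, model.means, model.sds)
        ]
    )
    return model.intercept + Z @ model.coef


def aqi_feature_matrix(
    cohort: Sequence[SubjectRecord],
    regions: Sequence[str],
    params: AQIParams = AQIParams(),
) -> pd.DataFrame:
    """Per-subject-per-region index matrix (subjects as rows, indexed by id)."""
    data = {
        r: [aqi_value(s.tacs[r], params) for s in cohort] for r in regions
    }
    return pd.DataFrame(data, index=[s.subject_id for s in cohort])
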