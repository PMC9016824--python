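"""End-to-end study pipeline on simulated (or user-supplied) cohorts.

Chains the stages in the order a full analysis runs them: simulate (or read)
a training and a held-out testing cohort -> quantify the three measures ->
optionally grid-search the index parameters -> lasso-select featured
regions -> fit the composite index -> evaluate each measure by stratified
CV on the training set and with the training-derived threshold on the
testing set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluate, optimize_select, quantify, simulate
from .frames import SubjectRecord
from .io_tables import RunConfig
from .quantify import AQIParams, QuantWindow

__all__ = ["PipelineResult", "run_pipeline", "quantify_cohort"]

logger = logging.getLogger(__name__)

#: regions whose mean SUVR/DVR forms the conventional composite comparator
DEFAULT_AMYLOID_REGIONS = ("caudal_anterior_cingulate", "caudate")


def quantify_cohort(
    cohort: Sequence[SubjectRecord],
    params: AQIParams = AQIParams(),
    window: QuantWindow = QuantWindow(),
    amyloid_regions: Sequence[str] = DEFAULT_AMYLOID_REGIONS,
) -> pd.DataFrame:
    """Per-subject measures table: AQI_roi per target region plus composite
    SUVR and DVR (mean over ``amyloid_regions``).

    Returns one row per subject with columns ``aqi__<region>`` for every
    non-reference region, ``suvr``, ``dvr``, ``group``, ``mmse``,
    ``cdr_sob``, indexed by subject id.
    """
    rows = []
    for s in cohort:
        ref = s.tacs.get(window.reference_region)
        if ref is None:
            raise ValueError(
                f"subject {s.subject_id}: reference region "
                f"{window.reference_region!r} missing"
            )
        row: Dict[str, object] = {
            "group": s.group,
            "mmse": s.mmse,
            "cdr_sob": s.cdr_sob,
        }
        for region in s.regions:
            if region == window.reference_region:
                continue
            row[f"aqi__{region}"] = quantify.aqi_value(s.tacs[region], params)
        suvrs = [
            quantify.compute_suvr(s.tacs[r], ref, window).value
            for r in amyloid_regions
            if r in s.tacs
        ]
        dvrs = [
            quantify.logan_dvr(s.tacs[r], ref, window).value
            for r in amyloid_regions
            if r in s.tacs
        ]
        if not suvrs:
            raise ValueError(
                f"subject {s.subject_id}: none of the amyloid regions "
                f"{tuple(amyloid_regions)} present"
            )
        row["suvr"] = float(np.mean(suvrs))
        row["dvr"] = float(np.mean(dvrs))
        rows.append((s.subject_id, row))
    return pd.DataFrame({k: v for k, v in rows}).T.infer_objects()


@dataclass
class PipelineResult:
    """Artifacts of one full pipeline run."""

    config: RunConfig
    train_subjects: List[SubjectRecord]
    test_subjects: List[SubjectRecord]
    train_measures: pd.DataFrame
    test_measures: pd.DataFrame
    aqi_params: AQIParams
    grid_result: Optional[optimize_select.GridResult]
    selection: optimize_select.LassoSelection
    overall_model: optimize_select.OverallIndexModel
    train_reports: Dict[str, evaluate.EvaluationReport]
    test_reports: Dict[str, evaluate.EvaluationReport]

    def report_table(self, which: str = "train") -> pd.DataFrame:
        """Classification-performance table (rows: AUC .. threshold)."""
        reports = self.train_reports if which == "train" else self.test_reports
        cols = {}
        for name, rep in reports.items():
            cols[name] = [
                rep.auc,
                rep.sensitivity,
                rep.specificity,
                rep.accuracy,
                rep.optimal_threshold,
            ]
        return pd.DataFrame(
            cols,
            index=["auc", "sensitivity", "specificity", "accuracy", "optimal_threshold"],
        )


def _seeded(config: RunConfig, seed: Optional[int]) -> RunConfig:
    if seed is None:
        return config
    sim = config.simulate.model_copy(update={"seed": int(seed) % 2**31})
    cv = config.cv.model_copy(update={"seed": (int(seed) + 1) % 2**31})
    return config.model_copy(update={"simulate": sim, "cv": cv})


def run_pipeline(
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
    train_subjects: Optional[Sequence[SubjectRecord]] = None,
    test_subjects: Optional[Sequence[SubjectRecord]] = None,
) -> PipelineResult:
    """Run the full study pipeline.

    Cohorts are simulated from ``config.simulate`` unless given explicitly.
    ``seed`` overrides both the simulation and CV seeds (testing cohort uses
    a derived seed so it is distinct from training).
    """
    config = _seeded(config or RunConfig(), seed)
    sim = config.simulate
    if train_subjects is None:
        logger.info("simulating training cohort (n=%d+%d)", sim.n_ad, sim.n_hc)
        cc = simulate.CohortConfig(
            n_ad=sim.n_ad,
            n_hc=sim.n_hc,
            noise_level=sim.noise_level,
            dose_range_mci=(sim.dose_min_mci, sim.dose_max_mci),
            seed=sim.seed,
        )
        train_subjects, _ = simulate.generate_cohort(cc)
    else:
        train_subjects = list(train_subjects)
    if test_subjects is None:
        cc_test = simulate.CohortConfig(
            n_ad=sim.n_ad_test,
            n_hc=sim.n_hc_test,
            noise_level=sim.noise_level,
            dose_range_mci=(sim.dose_min_mci, sim.dose_max_mci),
            seed=(sim.seed + 7919) % 2**31,
        )
        test_subjects, _ = simulate.generate_cohort(cc_test)
    else:
        test_subjects = list(test_subjects)

    window = QuantWindow(
        start=config.window.start,
        end=config.window.end,
        reference_region=config.window.reference_region,
    )
    params = AQIParams(a=config.aqi.a, t1=config.aqi.t1, t2=config.aqi.t2)

    grid_result = None
    if config.run_grid_search:
        g = config.grid
        grid = optimize_select.GridSpec(
            t1_range=(g.t1_min, g.t1_max),
            t1_step=g.t1_step,
            t2_range=(g.t2_min, g.t2_max),
            t2_step=g.t2_step,
            a_step=g.a_step,
        )
        grid_result = optimize_select.optimize_params(
            train_subjects,
            region=DEFAULT_AMYLOID_REGIONS[0],
            grid=grid,
            cv_folds=config.cv.folds,
            rng=config.cv.seed,
        )
        params = grid_result.best_params
        logger.info("grid search best params: %s", params)

    train_m = quantify_cohort(train_subjects, params, window)
    test_m = quantify_cohort(test_subjects, params, window)

    aqi_cols = [c for c in train_m.columns if c.startswith("aqi__")]
    features = train_m[aqi_cols].astype(float)
    features.columns = [c.removeprefix("aqi__") for c in aqi_cols]
    labels = train_m["group"].to_numpy()
    selection = optimize_select.lasso_select(
        features, labels, cv_folds=config.cv.folds, rng=config.cv.seed
    )
    selected = list(selection.regions) or [DEFAULT_AMYLOID_REGIONS[0]]
    logger.info("selected regions: %s", selected)

    overall = optimize_select.fit_overall(features[selected], labels)
    train_overall = optimize_select.apply_overall(overall, features[selected])
    test_features = test_m[[f"aqi__{r}" for r in selected]].astype(float)
    test_features.columns = selected
    test_overall = optimize_select.apply_overall(overall, test_features)

    train_vals = {
        "SUVR": train_m["suvr"].to_numpy(dtype=float),
        "DVR": train_m["dvr"].to_numpy(dtype=float),
        "AQI": train_overall,
    }
    test_vals = {
        "SUVR": test_m["suvr"].to_numpy(dtype=float),
        "DVR": test_m["dvr"].to_numpy(dtype=float),
        "AQI": test_overall,
    }
    mmse = train_m["mmse"].to_numpy(dtype=float)
    cdr = train_m["cdr_sob"].to_numpy(dtype=float)
    test_labels = test_m["group"].to_numpy()

    train_reports = {}
    test_reports = {}
    for name, vals in train_vals.items():
        rep = evaluate.evaluate_measure(
            vals,
            labels,
            k=config.cv.folds,
            rng=config.cv.seed,
            mmse=mmse,
            cdr_sob=cdr,
            measure_name=name,
        )
        train_reports[name] = rep
        thr = rep.optimal_threshold
        test_rep = evaluate.threshold_metrics(test_vals[name], test_labels, thr)
        test_rep.measure = name
        test_reports[name] = test_rep

    return PipelineResult(
        config=config,
        train_subjects=list(train_subjects),
        test_subjects=list(test_subjects),
        train_measures=train_m,
        test_measures=test_m,
        aqi_params=params,
        grid_result=grid_result,
        selection=selection,
        overall_model=overall,
        train_reports=train_reports,
        test_reports=test_reports,
    )
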