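"""Long-format TAC tables, measures tables, and run configuration.

The interchange format is one long CSV/TSV with a row per
(subject, region, frame):

    subject_id, group, region, frame_start_s, frame_duration_s,
    activity_bq_ml, injected_dose_mbq [, mmse, cdr_sob]

Times are seconds and dose is MBq (explicit unit suffixes in the header, so
there is nothing to guess).  Readers validate rather than repair: schedule
gaps or overlaps, inconsistent dose within a subject, or missing frames are
errors naming the offending subject.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .frames import FrameSchedule, SubjectRecord, TimeActivityCurve

__all__ = [
    "read_tac_table",
    "write_tac_table",
    "write_ground_truth",
    "measures_to_frame",
    "RunConfig",
    "load_config",
    "config_hash",
]

REQUIRED_COLUMNS = [
    "subject_id",
    "group",
    "region",
    "frame_start_s",
    "frame_duration_s",
    "activity_bq_ml",
    "injected_dose_mbq",
]
OPTIONAL_COLUMNS = ["mmse", "cdr_sob"]


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_tac_table(path: Union[str, Path], dialect: Optional[str] = None) -> List[SubjectRecord]:
    """Read a long-format TAC table into subject records.

    ``dialect`` may be "csv" or "tsv"; by default the delimiter is sniffed
    from the header line.  Frame schedules are reconstructed per subject and
    validated for contiguity; inconsistencies raise with the subject named.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t", None: _sniff_sep(path)}[dialect]
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TAC table missing required column(s): {missing}")

    subjects: List[SubjectRecord] = []
    for sid, sdf in df.groupby("subject_id", sort=False):
        doses = sdf["injected_dose_mbq"].unique()
        if len(doses) != 1:
            raise ValueError(f"subject {sid}: inconsistent injected dose {doses}")
        groups = sdf["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"subject {sid}: inconsistent group label {groups}")
        schedule: Optional[FrameSchedule] = None
        tacs: Dict[str, TimeActivityCurve] = {}
        for region, rdf in sdf.groupby("region", sort=False):
            rdf = rdf.sort_values("frame_start_s")
            try:
                sched = FrameSchedule(
                    rdf["frame_start_s"].to_numpy(dtype=float),
                    rdf["frame_duration_s"].to_numpy(dtype=float),
                )
            except ValueError as exc:
                raise ValueError(
                    f"subject {sid}, region {region}: invalid schedule: {exc}"
                ) from exc
            if schedule is None:
                schedule = sched
            elif sched != schedule:
                raise ValueError(
                    f"subject {sid}: region {region} schedule differs from the "
                    "subject's other regions"
                )
            tacs[str(region)] = TimeActivityCurve(
                region=str(region),
                schedule=sched,
                activity=rdf["activity_bq_ml"].to_numpy(dtype=float),
                injected_dose=float(doses[0]),
            )
        mmse = cdr = None
        if "mmse" in sdf.columns and sdf["mmse"].notna().any():
            mmse = float(sdf["mmse"].dropna().iloc[0])
        if "cdr_sob" in sdf.columns and sdf["cdr_sob"].notna().any():
            cdr = float(sdf["cdr_sob"].dropna().iloc[0])
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                group=str(groups[0]),
                tacs=tacs,
                mmse=mmse,
                cdr_sob=cdr,
            )
        )
    return subjects


def write_tac_table(subjects: Sequence[SubjectRecord], path: Union[str, Path]) -> None:
    """Write subjects to a long-format CSV (deterministic row order:
    subject, region, frame; floats serialized with repr round-trip safety)."""
    rows = []
    for s in subjects:
        for region in s.regions:
            tac = s.tacs[region]
            for i in range(tac.schedule.n_frames):
                rows.append(
                    (
                        s.subject_id,
                        s.group,
                        region,
                        tac.schedule.frame_start[i],
                        tac.schedule.frame_duration[i],
                        tac.activity[i],
                        tac.injected_dose,
                        s.mmse if s.mmse is not None else np.nan,
                        s.cdr_sob if s.cdr_sob is not None else np.nan,
                    )
                )
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
    df.to_csv(path, index=False)


def write_ground_truth(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the simulator's per-subject-per-region kinetic ground truth."""
    truth.to_csv(path, index=False)


def measures_to_frame(measures) -> pd.DataFrame:
    """Flatten RegionMeasure objects into a tidy measures table."""
    return pd.DataFrame(
        [(m.subject_id, m.region, m.measure, m.value) for m in measures],
        columns=["subject_id", "region", "measure", "value"],
    )


# ---------------------------------------------------------------------------
# run configuration


class AQISection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    a: float = 0.5
    t1: float = 1650.0
    t2: float = 1650.0


class WindowSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: float = 1800.0
    end: float = 3600.0
    reference_region: str = "cerebellar_cortex"


class GridSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t1_min: float = 50.0
    t1_max: float = 3300.0
    t1_step: float = 50.0
    t2_min: float = 300.0
    t2_max: float = 3300.0
    t2_step: float = 50.0
    a_step: float = 0.1


class CVSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    folds: int = 10
    seed: int = 0


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_ad: int = 50
    n_hc: int = 50
    n_ad_test: int = 10
    n_hc_test: int = 10
    noise_level: float = 5.0
    dose_min_mci: float = 6.0
    dose_max_mci: float = 20.0
    seed: int = 1234


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    aqi: AQISection = Field(default_factory=AQISection)
    window: WindowSection = Field(default_factory=WindowSection)
    grid: GridSection = Field(default_factory=GridSection)
    cv: CVSection = Field(default_factory=CVSection)
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    interp_step: float = 1.0  # seconds; fine-sampling step for interpolation
    run_grid_search: bool = False  # pipeline: optimize (a, t1, t2) before use


def load_config(path: Optional[Union[str, Path]]) -> RunConfig:
    """Load YAML/JSON config (or defaults when ``path`` is None)."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a config."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
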