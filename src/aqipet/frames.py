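"""Framed dynamic-PET time-activity curves.

A dynamic PET acquisition is a sequence of contiguous frames of known start
time and duration.  The mean activity concentration of a region over those
frames is its time-activity curve (TAC).  Throughout the package a frame's
activity is treated as the curve value at the frame *mid-time*, times are
seconds post injection-start, activity is Bq/ml, and injected dose is MBq.
Decay correction is assumed to have been applied upstream.

This module holds the three core containers (:class:`FrameSchedule`,
:class:`TimeActivityCurve`, :class:`SubjectRecord`) and the low-level TAC
operations (interpolation, peak finding, integration, truncation) everything
else builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "SubjectRecord",
    "pib_schedule",
    "mid_times",
    "interpolate_tac",
    "find_tmax",
    "trapezoid_integral",
    "truncate_to",
]

GROUPS = ("AD", "HC", "unknown")

#: tolerance for frame-boundary bookkeeping, seconds
_T_EPS = 1e-9


def _readonly_1d(x, name: str) -> np.ndarray:
    arr = np.array(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous framing of a dynamic scan.

    Parameters
    ----------
    frame_start : array-like
        Start time of each frame, seconds; ``frame_start[0]`` must be 0 and
        frames must be contiguous (``start[i+1] == start[i] + duration[i]``).
    frame_duration : array-like
        Duration of each frame, seconds; all strictly positive.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = _readonly_1d(self.frame_start, "frame_start")
        dur = _readonly_1d(self.frame_duration, "frame_duration")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if start.size != dur.size:
            raise ValueError("frame_start and frame_duration lengths differ")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(dur)):
            raise ValueError("frame times must be finite")
        if abs(start[0]) > _T_EPS:
            raise ValueError("first frame must start at t = 0")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        gaps = start[1:] - (start[:-1] + dur[:-1])
        if np.any(np.abs(gaps) > 1e-6):
            i = int(np.argmax(np.abs(gaps) > 1e-6))
            raise ValueError(
                f"frames must be contiguous: gap/overlap of {gaps[i]:g} s "
                f"before frame {i + 1}"
            )
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)

    @classmethod
    def from_durations(cls, durations: Sequence[float]) -> "FrameSchedule":
        """Build a schedule starting at 0 from frame durations alone."""
        dur = np.asarray(durations, dtype=float)
        start = np.concatenate(([0.0], np.cumsum(dur)[:-1]))
        return cls(start, dur)

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def mid_times(self) -> np.ndarray:
        """Frame middle times, seconds; strictly increasing."""
        return self.frame_start + self.frame_duration / 2.0

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1])

    def __eq__(self, other: object) -> bool:  # array fields need explicit eq
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.frame_start, other.frame_start) and np.array_equal(
            self.frame_duration, other.frame_duration
        )

    def __hash__(self) -> int:
        return hash((self.frame_start.tobytes(), self.frame_duration.tobytes()))


def pib_schedule() -> FrameSchedule:
    """The 60-min PiB acquisition framing: 12 x 10 s, 3 x 60 s, 11 x 5 min."""
    return FrameSchedule.from_durations([10.0] * 12 + [60.0] * 3 + [300.0] * 11)


@dataclass(frozen=True)
class TimeActivityCurve:
    """One region's framed activity concentrations plus the injected dose.

    ``activity[i]`` is the mean activity concentration (Bq/ml) over frame
    ``i``; by convention it is the curve value S(t) at the frame mid-time,
    and S(0) is defined as ``activity[0]`` (the first-frame average), not an
    extrapolation.  NaN marks a missing frame; infinities are rejected.
    """

    region: str
    schedule: FrameSchedule
    activity: np.ndarray
    injected_dose: float  # MBq

    def __post_init__(self) -> None:
        act = _readonly_1d(self.activity, "activity")
        if act.size != self.schedule.n_frames:
            raise ValueError(
                f"activity has {act.size} values for {self.schedule.n_frames} frames"
            )
        if np.any(np.isinf(act)):
            raise ValueError("activity values must not be infinite")
        if not (np.isfinite(self.injected_dose) and self.injected_dose > 0):
            raise ValueError("injected_dose must be a positive number of MBq")
        object.__setattr__(self, "activity", act)

    # Convenience delegates to the module-level operations.
    def interpolate(self, query_times):
        return interpolate_tac(self, query_times)

    def tmax(self) -> float:
        return find_tmax(self)

    def integral(self, upto: float) -> float:
        return trapezoid_integral(self, upto)

    def truncated(self, t_cut: float) -> "TimeActivityCurve":
        return truncate_to(self, t_cut)


@dataclass(frozen=True)
class SubjectRecord:
    """All TACs of one subject plus group label and clinical scores."""

    subject_id: str
    group: str
    tacs: Mapping[str, TimeActivityCurve]
    mmse: Optional[float] = None
    cdr_sob: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.tacs:
            raise ValueError(f"subject {self.subject_id}: no TACs")
        tacs = dict(self.tacs)
        for region, tac in tacs.items():
            if tac.region != region:
                raise ValueError(
                    f"subject {self.subject_id}: TAC keyed {region!r} is "
                    f"labelled {tac.region!r}"
                )
        first = next(iter(tacs.values()))
        for tac in tacs.values():
            if tac.schedule != first.schedule:
                raise ValueError(
                    f"subject {self.subject_id}: regions have different schedules"
                )
            if tac.injected_dose != first.injected_dose:
                raise ValueError(
                    f"subject {self.subject_id}: inconsistent injected dose"
                )
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"subject {self.subject_id}: MMSE outside [0, 30]")
        if self.cdr_sob is not None and self.cdr_sob < 0:
            raise ValueError(f"subject {self.subject_id}: negative CDR-SOB")
        object.__setattr__(self, "tacs", tacs)

    @property
    def schedule(self) -> FrameSchedule:
        return next(iter(self.tacs.values())).schedule

    @property
    def injected_dose(self) -> float:
        return next(iter(self.tacs.values())).injected_dose

    @property
    def regions(self) -> list:
        return list(self.tacs)


# ---------------------------------------------------------------------------
# operations


def mid_times(schedule: FrameSchedule) -> np.ndarray:
    """Frame middle times ``start + duration/2``, seconds."""
    return schedule.mid_times


def interpolate_tac(
    tac: TimeActivityCurve, query_times: Union[float, Sequence[float]]
) -> Union[float, np.ndarray]:
    """Piecewise-linear interpolation of the TAC over (mid-time, activity).

    Below the first mid-time the curve is held constant at ``activity[0]``
    (consistent with S(0) being the first-frame average).  Queries beyond the
    last mid-time raise: there is no principled extrapolation of a framed
    curve, and needing one indicates a caller bug.
    """
    q = np.asarray(query_times, dtype=float)
    mids = tac.schedule.mid_times
    last = mids[-1]
    if np.any(q < -_T_EPS) or np.any(q > last + _T_EPS):
        raise ValueError(
            f"query time out of range [0, {last:g}] s for region {tac.region!r}"
        )
    out = np.interp(np.clip(q, 0.0, last), mids, tac.activity)
    return float(out) if np.isscalar(query_times) else out


def find_tmax(tac: TimeActivityCurve) -> float:
    """Mid-time of the frame with maximal activity (earliest frame on ties)."""
    act = tac.activity
    if np.all(np.isnan(act)):
        raise ValueError(f"region {tac.region!r}: all-NaN activity, no peak")
    idx = int(np.nanargmax(act))  # first occurrence on ties
    return float(tac.schedule.mid_times[idx])


def trapezoid_integral(tac: TimeActivityCurve, upto: float) -> float:
    """Trapezoidal integral of the piecewise-linear TAC from 0 to ``upto``.

    The point (0, activity[0]) is prepended so the integral starts at scan
    start; the segment from 0 to the first mid-time is therefore flat.
    Returns Bq*s/ml.
    """
    if upto < 0:
        raise ValueError("integration endpoint must be non-negative")
    if upto == 0:
        return 0.0
    mids = tac.schedule.mid_times
    inner = mids[(mids > 0) & (mids < upto)]
    xs = np.concatenate(([0.0], inner, [upto]))
    ys = np.concatenate(
        ([tac.activity[0]], interpolate_tac(tac, inner), [interpolate_tac(tac, upto)])
    )
    return float(np.trapezoid(ys, xs))


def truncate_to(tac: TimeActivityCurve, t_cut: float) -> TimeActivityCurve:
    """Keep only frames whose end time is <= ``t_cut`` seconds.

    Used to demonstrate that the short-scan index needs no frame ending
    after 30 min.
    """
    if t_cut <= 0:
        raise ValueError("t_cut must be positive")
    keep = tac.schedule.frame_end <= t_cut + _T_EPS
    if not np.any(keep):
        raise ValueError(f"t_cut={t_cut:g} s leaves no complete frame")
    n = int(np.count_nonzero(keep))
    if n < tac.schedule.n_frames and not np.all(keep[:n]):
        raise ValueError("frames ending before t_cut are not a prefix")  # unreachable
    sched = FrameSchedule(tac.schedule.frame_start[:n], tac.schedule.frame_duration[:n])
    return TimeActivityCurve(
        region=tac.region,
        schedule=sched,
        activity=tac.activity[:n],
        injected_dose=tac.injected_dose,
    )
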