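"""Region-level amyloid measures: AQI_roi, SUVR, and reference-Logan DVR.

The amyloid quantification index for one region combines two slopes read off
the first 30 minutes of the TAC,

    AQI_roi = a * (S(t1) - S(0)) / t1
              - (1 - a) * (S(t_max) - S(t2)) / (t2 - t_max),

dose-normalized by the injected activity (MBq).  The first slope measures
mid-phase tracer retention (start to t1); the second measures the clearance
rate from the peak frame at t_max down to t2.  Amyloid-positive tissue shows
greater retention and slower clearance, so both terms push AQI_roi upward.
With the optimized defaults a = 0.5 and t1 = t2 = 1650 s, no sample after
1650 s (< 30 min) enters the computation.

SUVR and DVR are the conventional late-window comparators, computed over
30-60 min post injection against a cerebellar-cortex reference: SUVR as the
ratio of duration-weighted window means, DVR as the slope of the reference
Logan plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import (
    TimeActivityCurve,
    find_tmax,
    interpolate_tac,
    trapezoid_integral,
)

__all__ = [
    "AQIParams",
    "QuantWindow",
    "RegionMeasure",
    "compute_aqi_roi",
    "aqi_value",
    "compute_suvr",
    "logan_dvr",
]


@dataclass(frozen=True)
class AQIParams:
    """The (a, t1, t2) triple of the two-slope index.

    ``a`` in [0, 1] weights retention against clearance; t1 and t2 are the
    slope endpoints in seconds.  Defaults are the optimized values
    a = 0.5, t1 = t2 = 1650 s.  The constraint t2 > t_max is TAC-dependent
    and enforced at computation time.
    """

    a: float = 0.5
    t1: float = 1650.0
    t2: float = 1650.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("weight a must lie in [0, 1]")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive seconds")


@dataclass(frozen=True)
class QuantWindow:
    """Late-scan window and reference region for SUVR/DVR.

    Default 1800-3600 s (30-60 min post injection, closed interval on frame
    mid-times) with the cerebellar cortex as reference.
    """

    start: float = 1800.0
    end: float = 3600.0
    reference_region: str = "cerebellar_cortex"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")

    def frame_mask(self, tac: TimeActivityCurve) -> np.ndarray:
        mids = tac.schedule.mid_times
        return (mids >= self.start - 1e-9) & (mids <= self.end + 1e-9)


@dataclass(frozen=True)
class RegionMeasure:
    """One (subject, region, measure) value.

    AQI_roi is a dose-normalized slope difference, (Bq/ml/s)/MBq, and may
    take either sign; SUVR and DVR are positive unitless ratios.
    """

    subject_id: str
    region: str
    measure: str
    value: float


def aqi_value(tac: TimeActivityCurve, params: AQIParams = AQIParams()) -> float:
    """Dose-normalized AQI_roi of one TAC (scalar fast path)."""
    mids = tac.schedule.mid_times
    last = float(mids[-1])
    if params.t1 > last + 1e-9 or params.t2 > last + 1e-9:
        raise ValueError(
            f"t1/t2 beyond the scanned range [0, {last:g}] s "
            f"for region {tac.region!r}"
        )
    tmax = find_tmax(tac)
    if params.t2 <= tmax:
        raise ValueError(
            f"t2={params.t2:g} s must exceed the peak time t_max={tmax:g} s; "
            "the clearance slope is undefined otherwise"
        )
    s0 = float(tac.activity[0])
    s_t1 = interpolate_tac(tac, float(params.t1))
    s_t2 = interpolate_tac(tac, float(params.t2))
    s_max = interpolate_tac(tac, tmax)  # frame value at the peak frame mid-time
    raw = params.a * (s_t1 - s0) / params.t1 - (1.0 - params.a) * (s_max - s_t2) / (
        params.t2 - tmax
    )
    return raw / tac.injected_dose


def compute_aqi_roi(
    tac: TimeActivityCurve,
    params: AQIParams = AQIParams(),
    subject_id: str = "",
) -> RegionMeasure:
    """AQI_roi of one region as a :class:`RegionMeasure`."""
    return RegionMeasure(
        subject_id=subject_id,
        region=tac.region,
        measure="AQI_roi",
        value=aqi_value(tac, params),
    )


def _window_frames(
    target: TimeActivityCurve, reference: TimeActivityCurve, window: QuantWindow
) -> np.ndarray:
    if target.schedule != reference.schedule:
        raise ValueError("target and reference must share a frame schedule")
    mask = window.frame_mask(target)
    n = int(np.count_nonzero(mask))
    if n < 2:
        raise ValueError(
            f"window [{window.start:g}, {window.end:g}] s covers {n} frame "
            "mid-times; at least 2 are required"
        )
    return mask


def compute_suvr(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    window: QuantWindow = QuantWindow(),
    subject_id: str = "",
) -> RegionMeasure:
    """Standardized uptake value ratio over the late window.

    Ratio of duration-weighted mean activity of target to reference over the
    frames whose mid-times fall in the window.  (On the standard schedule
    all window frames share one duration, so the weighting is a no-op there;
    it matters for irregular schedules.)
    """
    mask = _window_frames(target, reference, window)
    w = target.schedule.frame_duration[mask]
    mean_t = float(np.sum(target.activity[mask] * w) / np.sum(w))
    mean_r = float(np.sum(reference.activity[mask] * w) / np.sum(w))
    if mean_r <= 0:
        raise ValueError("reference-region window mean is non-positive")
    return RegionMeasure(
        subject_id=subject_id,
        region=target.region,
        measure="SUVR",
        value=mean_t / mean_r,
    )


def logan_dvr(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    window: QuantWindow = QuantWindow(),
    subject_id: str = "",
    k2_ref: float | None = None,
) -> RegionMeasure:
    """Distribution volume ratio from the reference Logan plot.

    For each window frame i at mid-time t_i,

        y_i = int_0^{t_i} C_T dt / C_T(t_i),
        x_i = [ int_0^{t_i} C_ref dt (+ C_ref(t_i)/k2_ref) ] / C_T(t_i),

    and DVR is the ordinary-least-squares slope of y on x.  The optional
    population-clearance correction term C_ref/k2_ref is off by default
    (``k2_ref=None``); ``k2_ref`` is in 1/min when given.
    """
    mask = _window_frames(target, reference, window)
    mids = target.schedule.mid_times[mask]
    ct = target.activity[mask]
    if np.any(ct <= 0):
        raise ValueError(
            "target activity must be positive at every window frame for the "
            "Logan plot"
        )
    int_t = np.array([trapezoid_integral(target, float(t)) for t in mids])
    int_r = np.array([trapezoid_integral(reference, float(t)) for t in mids])
    if k2_ref is not None:
        if k2_ref <= 0:
            raise ValueError("k2_ref must be positive (1/min)")
        int_r = int_r + reference.activity[mask] / (k2_ref / 60.0)
    y = int_t / ct
    x = int_r / ct
    slope = float(np.polyfit(x, y, 1)[0])
    return RegionMeasure(
        subject_id=subject_id,
        region=target.region,
        measure="DVR",
        value=slope,
    )
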