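"""Synthetic dynamic-PiB-PET cohort generator with known kinetic ground truth.

The generative chain is: a Feng-type tri-exponential arterial input function
Cp(t) (scaled by injected dose), a one-tissue-compartment reference region
(cerebellar cortex, devoid of specific binding), and target-region curves
produced by the simplified reference tissue model (SRTM)

    C_T(t) = R1 * C_ref(t) + (k2 - R1 * k2a) * (C_ref (x) exp(-k2a t)),
    k2a = k2 / (1 + BPND),

so every simulated region has an exact ground-truth distribution volume
ratio DVR = 1 + BPND without any arterial-sampling assumptions.  Curves are
computed on a fine grid (0.5 s), averaged over each frame of the acquisition
schedule (mirroring real frame integration), and perturbed with
heteroscedastic Gaussian noise whose variance scales like activity/duration
(shorter frames are noisier, as count statistics dictate).

The default presets emulate a PiB study: amyloid-positive (AD) subjects draw
higher binding potential and lower relative delivery R1 in cortical target
regions than healthy controls (slower clearance, greater retention), while
the cerebellar-cortex reference uses the same kinetics distribution in both
groups.  Doses are uniform in 6-20 mCi (stored as MBq), and MMSE / CDR-SOB
scores are monotone functions of the subject's mean target binding plus
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .frames import FrameSchedule, SubjectRecord, TimeActivityCurve, pib_schedule

__all__ = [
    "AIFParams",
    "RegionKinetics",
    "KineticsPrior",
    "CohortConfig",
    "aif",
    "reference_fine",
    "reference_tac",
    "srtm_tac",
    "add_noise",
    "generate_cohort",
    "DEFAULT_AIF_PER_MBQ",
    "DEFAULT_REGION_PRIORS",
    "MCI_PER_MBQ",
]

MBQ_PER_MCI = 37.0
MCI_PER_MBQ = 1.0 / MBQ_PER_MCI

#: fine simulation grid step, seconds
DEFAULT_DT = 0.5


@dataclass(frozen=True)
class AIFParams:
    """Feng-type tri-exponential arterial input function.

    Cp(t) = 0 for t < delay, and for s = t - delay

        Cp = (A1*s - A2 - A3) * exp(-lambda1*s)
             + A2 * exp(-lambda2*s) + A3 * exp(-lambda3*s)

    with lambda1 > lambda2 > lambda3 > 0 so the curve rises sharply, peaks
    early, and decays with a slow metabolite-like tail.
    """

    A1: float  # Bq/ml/s
    A2: float  # Bq/ml
    A3: float  # Bq/ml
    lambda1: float  # 1/s
    lambda2: float  # 1/s
    lambda3: float  # 1/s
    delay: float = 0.0  # s

    def __post_init__(self) -> None:
        if not (self.lambda1 > self.lambda2 > self.lambda3 > 0):
            raise ValueError("require lambda1 > lambda2 > lambda3 > 0")
        if self.A1 < 0 or self.delay < 0:
            raise ValueError("A1 and delay must be non-negative")
        # non-negativity of Cp over the hour, checked on a coarse grid
        t = np.arange(0.0, 3600.0 + 1.0, 1.0)
        cp = aif(t, self, _validate=False)
        if np.any(cp < -1e-9 * max(cp.max(), 1.0)):
            raise ValueError("parameters produce a negative input function")

    def scaled(self, factor: float) -> "AIFParams":
        """Same shape with all amplitudes multiplied by ``factor``."""
        return replace(self, A1=self.A1 * factor, A2=self.A2 * factor, A3=self.A3 * factor)


def aif(t, params: AIFParams, _validate: bool = True):
    """Evaluate the arterial input function at times ``t`` (seconds)."""
    tt = np.asarray(t, dtype=float) - params.delay
    if _validate and np.any(np.asarray(t, dtype=float) < 0):
        raise ValueError("time must be non-negative")
    s = np.clip(tt, 0.0, None)
    cp = (
        (params.A1 * s - params.A2 - params.A3) * np.exp(-params.lambda1 * s)
        + params.A2 * np.exp(-params.lambda2 * s)
        + params.A3 * np.exp(-params.lambda3 * s)
    )
    cp = np.where(tt < 0, 0.0, cp)
    return float(cp) if np.isscalar(t) else cp


#: input-function shape per MBq injected; amplitudes are multiplied by the
#: injected dose (MBq) for each subject.  Chosen so tissue curves peak within
#: 4 min of injection and frame peak times fall in the 80-240 s band.
DEFAULT_AIF_PER_MBQ = AIFParams(
    A1=28.0,  # Bq/ml/s per MBq
    A2=1.4,  # Bq/ml per MBq
    A3=1.0,  # Bq/ml per MBq (slow metabolite-like tail)
    lambda1=0.042,
    lambda2=0.006,
    lambda3=0.00022,
    delay=15.0,
)


@dataclass(frozen=True)
class RegionKinetics:
    """SRTM ground truth for one region: relative delivery R1, tissue
    clearance k2 (1/min), and binding potential BPND."""

    R1: float
    k2: float  # 1/min
    BPND: float

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.k2 <= 0 or self.BPND < 0:
            raise ValueError("require R1 > 0, k2 > 0, BPND >= 0")

    @property
    def k2a(self) -> float:
        """Apparent clearance k2 / (1 + BPND), 1/min."""
        return self.k2 / (1.0 + self.BPND)

    @property
    def dvr_true(self) -> float:
        return 1.0 + self.BPND


# ---------------------------------------------------------------------------
# numerics


def convolve_exponential(u: np.ndarray, k: float, dt: float) -> np.ndarray:
    """(u (x) exp(-k t)) on a uniform grid, exact for piecewise-linear u.

    Uses the recursive update y[i+1] = y[i]*exp(-k dt) + analytic increment,
    which is well-conditioned for any k*dt (unlike naive discrete
    convolution).  k = 0 degenerates to the running integral.
    """
    u = np.asarray(u, dtype=float)
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    if k == 0.0:
        return cumulative_trapezoid(u, dx=dt, initial=0.0)
    ekh = math.exp(-k * dt)
    alpha = (1.0 - ekh) / k
    beta = (dt - alpha) / k
    c1 = beta / dt
    c0 = alpha - c1
    # y[n] = c1*u[n] + c0*u[n-1] + ekh*y[n-1], with y[0] forced to 0
    zi = np.array([-c1 * u[0]])
    y, _ = lfilter([c1, c0], [1.0, -ekh], u, zi=zi)
    return y


def frame_average(
    t_fine: np.ndarray, y_fine: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Average a fine-grid curve over each frame of ``schedule``."""
    if t_fine[-1] < schedule.total_duration - 1e-6:
        raise ValueError("fine grid does not cover the schedule")
    F = cumulative_trapezoid(y_fine, t_fine, initial=0.0)
    bounds = np.concatenate((schedule.frame_start, [schedule.total_duration]))
    Fb = np.interp(bounds, t_fine, F)
    return np.diff(Fb) / schedule.frame_duration


def fine_grid(schedule: FrameSchedule, dt: float = DEFAULT_DT) -> np.ndarray:
    return np.arange(0.0, schedule.total_duration + dt / 2, dt)


# ---------------------------------------------------------------------------
# curve generation


def reference_fine(
    aif_params: AIFParams,
    K1_ref: float,
    k2_ref: float,
    t_fine: np.ndarray,
) -> np.ndarray:
    """One-tissue-compartment reference curve on a fine grid.

    C_ref(t) = K1_ref * (Cp (x) exp(-k2_ref t)), with K1_ref in ml/ml/min and
    k2_ref in 1/min (converted to per-second internally).
    """
    if K1_ref < 0 or k2_ref <= 0:
        raise ValueError("require K1_ref >= 0 and k2_ref > 0")
    dt = float(t_fine[1] - t_fine[0])
    cp = aif(t_fine, aif_params)
    return (K1_ref / 60.0) * convolve_exponential(cp, k2_ref / 60.0, dt)


def reference_tac(
    aif_params: AIFParams,
    K1_ref: float,
    k2_ref: float,
    schedule: FrameSchedule,
    injected_dose: float = 1.0,
    region: str = "cerebellar_cortex",
    dt: float = DEFAULT_DT,
) -> TimeActivityCurve:
    """Frame-averaged reference-region TAC from the 1TC solution."""
    t = fine_grid(schedule, dt)
    fine = reference_fine(aif_params, K1_ref, k2_ref, t)
    return TimeActivityCurve(
        region=region,
        schedule=schedule,
        activity=frame_average(t, fine, schedule),
        injected_dose=injected_dose,
    )


def srtm_fine(
    ref_fine_curve: np.ndarray, kin: RegionKinetics, dt: float
) -> np.ndarray:
    """SRTM target curve on the same fine grid as the reference curve."""
    k2a_s = kin.k2a / 60.0
    coef = kin.k2 / 60.0 - kin.R1 * k2a_s
    return kin.R1 * ref_fine_curve + coef * convolve_exponential(
        ref_fine_curve, k2a_s, dt
    )


def srtm_tac(
    ref: Tuple[np.ndarray, np.ndarray],
    kin: RegionKinetics,
    schedule: FrameSchedule,
    injected_dose: float = 1.0,
    region: str = "target",
) -> TimeActivityCurve:
    """Frame-averaged SRTM target TAC.

    ``ref`` is the fine-grid reference curve as a ``(times, values)`` pair
    (uniform grid); with R1 = 1 and BPND = 0 the target equals the reference.
    """
    t_fine, y_fine = (np.asarray(a, dtype=float) for a in ref)
    dt = float(t_fine[1] - t_fine[0])
    fine = srtm_fine(y_fine, kin, dt)
    return TimeActivityCurve(
        region=region,
        schedule=schedule,
        activity=frame_average(t_fine, fine, schedule),
        injected_dose=injected_dose,
    )


def add_noise(
    tac: TimeActivityCurve, noise_level: float, rng
) -> TimeActivityCurve:
    """Add zero-mean Gaussian noise with sd = noise_level * sqrt(max(S,0)/dur).

    The variance scales with activity and inversely with frame duration,
    mimicking count statistics; values are not clipped (negative activities
    occur in real reconstructions).  Deterministic under a seeded generator.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    rng = np.random.default_rng(rng)
    sd = noise_level * np.sqrt(
        np.clip(tac.activity, 0.0, None) / tac.schedule.frame_duration
    )
    noisy = tac.activity + rng.standard_normal(tac.activity.size) * sd
    return TimeActivityCurve(
        region=tac.region,
        schedule=tac.schedule,
        activity=noisy,
        injected_dose=tac.injected_dose,
    )


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class KineticsPrior:
    """Normal priors for (R1, k2, BPND); BPND truncated at 0."""

    r1_mean: float
    r1_sd: float
    k2_mean: float  # 1/min
    k2_sd: float
    bp_mean: float
    bp_sd: float

    def draw(self, rng: np.random.Generator) -> RegionKinetics:
        r1 = max(0.1, rng.normal(self.r1_mean, self.r1_sd))
        k2 = max(0.02, rng.normal(self.k2_mean, self.k2_sd))
        bp = max(0.0, rng.normal(self.bp_mean, self.bp_sd))
        return RegionKinetics(R1=r1, k2=k2, BPND=bp)


#: per-region, per-group kinetic priors.  The two featured amyloid regions
#: carry the group signal (AD: higher BPND, lower R1); the remaining cortical
#: regions are amyloid-sparse in both groups; the cerebellar cortex is the
#: reference and is generated by the 1TC model with group-independent
#: parameters.
DEFAULT_REGION_PRIORS: Mapping[str, Mapping[str, KineticsPrior]] = {
    "caudal_anterior_cingulate": {
        "AD": KineticsPrior(0.85, 0.05, 0.15, 0.02, 0.90, 0.25),
        "HC": KineticsPrior(1.00, 0.05, 0.15, 0.02, 0.10, 0.05),
    },
    "caudate": {
        "AD": KineticsPrior(0.85, 0.05, 0.17, 0.02, 0.55, 0.15),
        "HC": KineticsPrior(1.00, 0.05, 0.17, 0.02, 0.08, 0.04),
    },
    "precentral": {
        "AD": KineticsPrior(1.00, 0.05, 0.16, 0.02, 0.05, 0.03),
        "HC": KineticsPrior(1.00, 0.05, 0.16, 0.02, 0.05, 0.03),
    },
    "pericalcarine": {
        "AD": KineticsPrior(1.00, 0.05, 0.16, 0.02, 0.05, 0.03),
        "HC": KineticsPrior(1.00, 0.05, 0.16, 0.02, 0.05, 0.03),
    },
}

#: reference-region (cerebellar cortex) 1TC priors, identical across groups
REFERENCE_K1_MEAN, REFERENCE_K1_SD = 0.30, 0.03  # ml/ml/min
REFERENCE_K2_MEAN, REFERENCE_K2_SD = 0.15, 0.012  # 1/min


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the acquisition the package targets: the 60-min PiB
    frame schedule, 6-20 mCi injected dose, 50 + 50 subjects, and
    group-dependent kinetics in the two featured amyloid regions.  A fixed
    seed yields a byte-identical cohort.
    """

    n_ad: int = 50
    n_hc: int = 50
    regions: Tuple[str, ...] = (
        "caudal_anterior_cingulate",
        "caudate",
        "precentral",
        "pericalcarine",
        "cerebellar_cortex",
    )
    reference_region: str = "cerebellar_cortex"
    priors: Mapping[str, Mapping[str, KineticsPrior]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PRIORS)
    )
    noise_level: float = 5.0
    dose_range_mci: Tuple[float, float] = (6.0, 20.0)
    aif_per_mbq: AIFParams = DEFAULT_AIF_PER_MBQ
    schedule: FrameSchedule = field(default_factory=pib_schedule)
    dt: float = DEFAULT_DT
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_ad < 0 or self.n_hc < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not self.regions:
            raise ValueError("region list must not be empty")
        if self.reference_region not in self.regions:
            raise ValueError(
                f"reference region {self.reference_region!r} missing from regions"
            )
        for r in self.regions:
            if r != self.reference_region and r not in self.priors:
                raise ValueError(f"no kinetic prior for region {r!r}")
        lo, hi = self.dose_range_mci
        if not (0 < lo <= hi):
            raise ValueError("invalid dose range")


def _clinical_scores(
    group: str, mean_bp: float, rng: np.random.Generator
) -> Tuple[float, float]:
    """MMSE and CDR-SOB as monotone functions of mean target binding."""
    mmse = np.clip(round(29.6 - 5.5 * mean_bp + rng.normal(0.0, 1.5)), 0, 30)
    if group == "HC":
        cdr = 0.0
    else:
        cdr = float(np.clip(0.5 + 4.0 * mean_bp + rng.normal(0.0, 1.2), 0.5, 9.0))
        cdr = round(cdr * 2) / 2  # CDR-SOB is scored in half points
    return float(mmse), cdr


def generate_cohort(
    config: CohortConfig = CohortConfig(),
) -> Tuple[List[SubjectRecord], pd.DataFrame]:
    """Simulate a cohort; returns (subjects, ground-truth table).

    The ground-truth table has one row per subject-region with the drawn
    (R1, k2, BPND) and the implied true DVR = 1 + BPND (reference rows carry
    R1 = 1, BPND = 0, DVR = 1).
    """
    rng = np.random.default_rng(config.seed)
    subjects: List[SubjectRecord] = []
    truth_rows: List[dict] = []
    t_fine = fine_grid(config.schedule, config.dt)
    target_regions = [r for r in config.regions if r != config.reference_region]
    signal = [  # regions carrying an amyloid (binding) group difference
        r
        for r in target_regions
        if abs(config.priors[r]["AD"].bp_mean - config.priors[r]["HC"].bp_mean) > 0.1
    ]

    labels = [("AD", i + 1) for i in range(config.n_ad)] + [
        ("HC", i + 1) for i in range(config.n_hc)
    ]
    for group, number in labels:
        subject_id = f"{group}_{number:03d}"
        dose_mci = rng.uniform(*config.dose_range_mci)
        dose_mbq = dose_mci * MBQ_PER_MCI
        amp = dose_mbq * math.exp(rng.normal(0.0, 0.05))
        delay = rng.uniform(10.0, 20.0)
        aifp = replace(config.aif_per_mbq.scaled(amp), delay=delay)

        k1_ref = max(0.05, rng.normal(REFERENCE_K1_MEAN, REFERENCE_K1_SD))
        k2_ref = max(0.02, rng.normal(REFERENCE_K2_MEAN, REFERENCE_K2_SD))
        ref_curve = reference_fine(aifp, k1_ref, k2_ref, t_fine)

        tacs: Dict[str, TimeActivityCurve] = {}
        ref_tac = TimeActivityCurve(
            region=config.reference_region,
            schedule=config.schedule,
            activity=frame_average(t_fine, ref_curve, config.schedule),
            injected_dose=dose_mbq,
        )
        tacs[config.reference_region] = add_noise(ref_tac, config.noise_level, rng)
        truth_rows.append(
            dict(
                subject_id=subject_id,
                group=group,
                region=config.reference_region,
                R1=1.0,
                k2=k2_ref,
                BPND=0.0,
                DVR_true=1.0,
            )
        )

        bp_signal: List[float] = []
        for region in target_regions:
            kin = config.priors[region][group].draw(rng)
            tac = srtm_tac(
                (t_fine, ref_curve),
                kin,
                config.schedule,
                injected_dose=dose_mbq,
                region=region,
            )
            tacs[region] = add_noise(tac, config.noise_level, rng)
            if region in signal:
                bp_signal.append(kin.BPND)
            truth_rows.append(
                dict(
                    subject_id=subject_id,
                    group=group,
                    region=region,
                    R1=kin.R1,
                    k2=kin.k2,
                    BPND=kin.BPND,
                    DVR_true=kin.dvr_true,
                )
            )

        mean_bp = float(np.mean(bp_signal)) if bp_signal else 0.0
        mmse, cdr_sob = _clinical_scores(group, mean_bp, rng)
        subjects.append(
            SubjectRecord(
                subject_id=subject_id,
                group=group,
                tacs=tacs,
                mmse=mmse,
                cdr_sob=cdr_sob,
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "group", "region", "R1", "k2", "BPND", "DVR_true"],
    )
    return subjects, truth
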