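import numpy as np
import pytest

from aqipet.frames import FrameSchedule, SubjectRecord, TimeActivityCurve, pib_schedule
from aqipet.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def schedule():
    return pib_schedule()


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort (50 AD + 50 HC, fixed seed)."""
    return generate_cohort(CohortConfig(seed=1234))


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 10+10 cohort for cheaper end-to-end checks."""
    return generate_cohort(CohortConfig(n_ad=10, n_hc=10, seed=42))


def make_tac(activity, durations=None, region="roi", dose=1.0, schedule=None):
    """Piecewise-linear TAC helper for hand-constructed fixtures."""
    activity = np.asarray(activity, dtype=float)
    if schedule is None:
        if durations is None:
            durations = [10.0] * activity.size
        schedule = FrameSchedule.from_durations(durations)
    return TimeActivityCurve(
        region=region, schedule=schedule, activity=activity, injected_dose=dose
    )


def make_subject(subject_id, group, tacs, **kw):
    return SubjectRecord(subject_id=subject_id, group=group, tacs=tacs, **kw)
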