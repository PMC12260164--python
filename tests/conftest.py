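import datetime as dt

import numpy as np
import pytest

from txlearn.encoding import EncodedCohort, PAD_ID
from txlearn.records import (
    BNF,
    ICD10,
    EventRecord,
    OutcomeDates,
    PatientRecord,
    WAVE1,
)


def make_patient(pid=0, age=65.0, sex="F", simd=5, diabetes=0, events=(),
                 outcome=None):
    p = PatientRecord(pid, age, sex, simd, diabetes, list(events),
                      outcome or OutcomeDates())
    p.sort_events()
    return p


def make_event(pid, day, code, system=BNF, wave=WAVE1):
    return EventRecord(pid, wave.lookback_start + dt.timedelta(days=day),
                       code, system)


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture
def event_factory():
    return make_event


def statics_only_cohort(statics: np.ndarray, vocab_size: int = 4,
                        max_len: int = 4) -> EncodedCohort:
    """An EncodedCohort with empty sequences; used to drive models from
    hand-specified static features alone."""
    n = len(statics)
    return EncodedCohort(
        np.arange(n),
        np.full((n, max_len), PAD_ID, dtype=np.int32),
        np.zeros((n, max_len), dtype=np.int32),
        np.zeros((n, max_len), dtype=bool),
        np.asarray(statics, dtype=np.float32),
        vocab_size,
    )


@pytest.fixture
def small_sim_cohort():
    """A small labelled single-wave simulated cohort shared across tests."""
    from txlearn.cohort import filter_eligible, label_wave
    from txlearn.records import STUDY_DRUGS
    from txlearn.simulate import null_scenario, simulate_cohort

    patients, truths = simulate_cohort(null_scenario(400, seed=7))
    eligible, _ = filter_eligible(patients, WAVE1.lookback_start)
    return label_wave(eligible, WAVE1, STUDY_DRUGS), truths
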