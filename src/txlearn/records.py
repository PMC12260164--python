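"""Core domain records shared across the pipeline.

The unit of analysis is a patient: static covariates (age, sex, SIMD
deprivation decile, diabetes status), a time-stamped stream of medical
codes (BNF dispensing codes, ICD-10 admission codes), and optional
outcome dates (first positive SARS-CoV-2 test, first COVID-19
hospitalisation, COVID-19 death).
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field

BNF = "BNF"
ICD10 = "ICD10"

_BNF_RE = re.compile(r"^\d{4,7}[0-9A-Za-z]*$")
_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.?\d{0,2})?$")


@dataclass(frozen=True, order=True)
class EventRecord:
    """One dated medical code (dispense or admission) for one patient."""

    patient_id: int
    event_date: dt.date
    code: str
    code_system: str  # BNF or ICD10

    def __post_init__(self) -> None:
        if self.code_system not in (BNF, ICD10):
            raise ValueError(f"unknown code system: {self.code_system!r}")
        pattern = _BNF_RE if self.code_system == BNF else _ICD10_RE
        if not pattern.match(self.code):
            raise ValueError(
                f"code {self.code!r} does not match the {self.code_system} dialect"
            )


def event_sort_key(e: EventRecord) -> tuple:
    # BNF sorts before ICD10 on same-day ties (alphabetical happens to agree,
    # but make the convention explicit).
    return (e.event_date, 0 if e.code_system == BNF else 1, e.code)


@dataclass
class OutcomeDates:
    """Dates of qualifying COVID-19 outcomes; any may be absent."""

    test_date: dt.date | None = None
    hosp_date: dt.date | None = None
    death_date: dt.date | None = None

    def earliest(self) -> dt.date | None:
        present = [d for d in (self.test_date, self.hosp_date, self.death_date) if d]
        return min(present) if present else None


@dataclass
class PatientRecord:
    """Static covariates + event stream + outcome dates."""

    patient_id: int
    age: float | None
    sex: str | None  # "F" or "M"
    simd_decile: int | None  # 1 (most deprived) .. 10
    diabetes: int | None
    events: list[EventRecord] = field(default_factory=list)
    outcome: OutcomeDates = field(default_factory=OutcomeDates)

    def sort_events(self) -> None:
        self.events.sort(key=event_sort_key)

    def has_complete_demographics(self) -> bool:
        return (
            self.age is not None
            and self.sex in ("F", "M")
            and self.simd_decile is not None
            and 1 <= self.simd_decile <= 10
            and self.diabetes is not None
        )


@dataclass(frozen=True)
class DrugClass:
    """A study drug class identified by its BNF code prefixes."""

    name: str
    bnf_prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.bnf_prefixes:
            raise ValueError("a drug class needs at least one BNF prefix")

    def matches(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.bnf_prefixes)


#: British National Formulary stems of the five study drug classes.
ACEI = DrugClass("ACEI", ("0205051",))
BB = DrugClass("BB", ("0204000",))
CCB = DrugClass("CCB", ("0206020",))
THZ = DrugClass("THZ", ("0202010",))
STATIN = DrugClass("STATIN", ("0212000B0", "0212000C0", "0212000X0", "0212000Y0"))

STUDY_DRUGS: tuple[DrugClass, ...] = (ACEI, BB, CCB, THZ, STATIN)


@dataclass(frozen=True)
class WaveDefinition:
    """A pandemic wave: exposure lookback window + follow-up window.

    Both windows are half-open ``[start, end)`` at day resolution and the
    lookback ends exactly where the follow-up starts.
    """

    wave_id: int
    lookback_start: dt.date
    lookback_end: dt.date
    followup_days: int = 180

    def __post_init__(self) -> None:
        if self.lookback_end <= self.lookback_start:
            raise ValueError("lookback window is empty or inverted")
        if self.followup_days <= 0:
            raise ValueError("followup_days must be positive")

    @property
    def followup_start(self) -> dt.date:
        return self.lookback_end

    @property
    def followup_end(self) -> dt.date:
        return self.followup_start + dt.timedelta(days=self.followup_days)

    def in_lookback(self, d: dt.date) -> bool:
        return self.lookback_start <= d < self.lookback_end


WAVE1 = WaveDefinition(1, dt.date(2019, 10, 1), dt.date(2020, 4, 1), 180)
WAVE2 = WaveDefinition(2, dt.date(2020, 4, 1), dt.date(2020, 10, 1), 180)


@dataclass
class LabeledPatient:
    """A patient labelled for one wave's analysis."""

    patient: PatientRecord
    wave_id: int
    exposure: dict[str, int]  # drug name -> 0/1
    y: int
    event_day: int  # day offset of the event, or followup_days if censored

    @property
    def patient_id(self) -> int:
        return self.patient.patient_id


@dataclass
class GroundTruth:
    """Simulator-only truth for one patient/wave: per-drug propensity and ITE."""

    patient_id: int
    wave_id: int
    true_propensity: dict[str, float]
    true_ite: dict[str, float]
    true_outcome_prob_treated: dict[str, float]
    true_outcome_prob_control: dict[str, float]
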