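"""Cohort construction: eligibility, exposure, outcome, wave splitting and
stratified undersampling of outcome-negative patients.

The design follows a two-wave case-control construction: the wave-1 pool
keeps all wave-1 cases plus a stratified random fraction of wave-1
negatives, where the keep-fraction equals (wave-1 cases / wave-2 cases);
the negatives removed in that step form an independent second-wave
cohort, re-labelled on the wave-2 lookback and follow-up windows.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (
    DrugClass,
    LabeledPatient,
    PatientRecord,
    WaveDefinition,
)

logger = logging.getLogger(__name__)

AGE_BANDS = ((40, 50), (50, 60), (60, 70), (70, 80), (80, 90), (90, 200))


def age_band(age: float) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age < hi:
            return f"{lo}-{hi - 1}" if hi < 200 else f"{lo}+"
    return "<40"


@dataclass
class ExclusionLog:
    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1

    def total(self) -> int:
        return sum(self.counts.values())


def filter_eligible(
    patients: list[PatientRecord],
    index_date: dt.date,
    min_age: float = 40.0,
) -> tuple[list[PatientRecord], ExclusionLog]:
    """Retain patients aged >= ``min_age`` at the index date with complete
    sex/age/SIMD. Ages are stored as of the study start, so the threshold
    is applied to the recorded age directly when the index date equals the
    study start; later index dates add the elapsed years."""
    log = ExclusionLog()
    kept = []
    for p in patients:
        if p.age is None:
            log.add("missing age")
            continue
        if p.sex not in ("F", "M"):
            log.add("missing sex")
            continue
        if p.simd_decile is None or not (1 <= p.simd_decile <= 10):
            log.add("missing SIMD")
            continue
        if p.age < min_age:
            log.add(f"age below {min_age:g}")
            continue
        kept.append(p)
    logger.info(
        "eligibility: kept %d of %d (%s)", len(kept), len(patients), log.counts
    )
    return kept, log


def define_exposure(
    patient: PatientRecord, drug: DrugClass, wave: WaveDefinition
) -> int:
    """1 iff >= 1 BNF dispensing event with one of the drug's prefixes and a
    date inside the half-open lookback window [start, end)."""
    for e in patient.events:
        if (
            e.code_system == "BNF"
            and wave.in_lookback(e.event_date)
            and drug.matches(e.code)
        ):
            return 1
    return 0


def is_prevalent(patient: PatientRecord, wave: WaveDefinition) -> bool:
    """True when a qualifying outcome predates the wave's follow-up start."""
    earliest = patient.outcome.earliest()
    return earliest is not None and earliest < wave.followup_start


def derive_outcome(
    patient: PatientRecord, wave: WaveDefinition
) -> tuple[int, int]:
    """(Y, event_day) for the 180-day composite endpoint.

    event_day is the day offset of the earliest qualifying outcome from
    followup_start; censored patients get Y=0 and event_day=followup_days.
    Prevalent outcomes (before followup_start) must be filtered out with
    :func:`is_prevalent` before calling.
    """
    earliest = patient.outcome.earliest()
    if earliest is None:
        return 0, wave.followup_days
    day = (earliest - wave.followup_start).days
    if day < 0:
        raise ValueError(
            f"patient {patient.patient_id}: outcome predates follow-up start"
        )
    if day < wave.followup_days:
        return 1, day
    return 0, wave.followup_days


def label_wave(
    patients: list[PatientRecord],
    wave: WaveDefinition,
    drugs: tuple[DrugClass, ...],
    log: ExclusionLog | None = None,
) -> list[LabeledPatient]:
    """Label exposures and the outcome for one wave, excluding (with a log
    entry) patients whose outcome predates the wave's follow-up."""
    out = []
    for p in patients:
        if is_prevalent(p, wave):
            if log is not None:
                log.add(f"prevalent case before wave {wave.wave_id} follow-up")
            continue
        y, day = derive_outcome(p, wave)
        exposure = {d.name: define_exposure(p, d, wave) for d in drugs}
        out.append(LabeledPatient(p, wave.wave_id, exposure, y, day))
    return out


def undersample_ratio(cases_w1: int, cases_w2: int) -> float:
    if cases_w2 <= 0:
        raise ValueError("cases_w2 must be positive")
    return cases_w1 / cases_w2


def undersample_negatives(
    wave1_pool: list[LabeledPatient],
    cases_w1: int,
    cases_w2: int,
    seed: int,
) -> tuple[list[LabeledPatient], list[LabeledPatient]]:
    """Thin the wave-1 negatives to the case ratio, stratified by
    (10-year age band, sex, SIMD decile).

    Every case is retained. Within each stratum each negative is kept
    independently with probability ratio = cases_w1 / cases_w2
    (deterministic given the seed); removed negatives are returned as the
    independent second-wave analysis pool.
    """
    ratio = undersample_ratio(cases_w1, cases_w2)
    if ratio >= 1.0:
        logger.warning("undersampling ratio %.3f >= 1: no-op", ratio)
        return list(wave1_pool), []
    strata: dict[tuple, list[LabeledPatient]] = {}
    kept: list[LabeledPatient] = []
    for lp in wave1_pool:
        if lp.y == 1:
            kept.append(lp)
        else:
            key = (age_band(lp.patient.age), lp.patient.sex,
                   lp.patient.simd_decile)
            strata.setdefault(key, []).append(lp)
    excluded: list[LabeledPatient] = []
    for stratum_idx, key in enumerate(sorted(strata, key=repr)):
        members = sorted(strata[key], key=lambda lp: lp.patient_id)
        # stratum index in sorted order keeps the draw reproducible
        rng = np.random.default_rng([seed, stratum_idx])
        draws = rng.random(len(members))
        for lp, u in zip(members, draws):
            (kept if u < ratio else excluded).append(lp)
    kept.sort(key=lambda lp: lp.patient_id)
    excluded.sort(key=lambda lp: lp.patient_id)
    return kept, excluded


@dataclass
class TwoWaveCohorts:
    wave1: list[LabeledPatient]
    wave2: list[LabeledPatient]
    ratio: float
    exclusions: ExclusionLog


def build_two_wave_cohorts(
    patients: list[PatientRecord],
    wave1: WaveDefinition,
    wave2: WaveDefinition,
    drugs: tuple[DrugClass, ...],
    seed: int,
) -> TwoWaveCohorts:
    """Full construction: eligibility, wave-1 labelling, undersampling of
    wave-1 negatives at the observed case ratio, and wave-2 re-labelling of
    the removed negatives."""
    eligible, log = filter_eligible(patients, wave1.lookback_start)
    w1_pool = label_wave(eligible, wave1, drugs, log)
    cases_w1 = sum(lp.y for lp in w1_pool)
    negatives = [lp for lp in w1_pool if lp.y == 0]
    # wave-2 case count among wave-1 negatives, assessed on wave-2 windows
    neg_patients = [lp.patient for lp in negatives]
    w2_all = label_wave(neg_patients, wave2, drugs, log)
    cases_w2 = sum(lp.y for lp in w2_all)
    if cases_w2 == 0:
        raise ValueError("no second-wave cases: cannot form the case ratio")
    w1_cohort, removed = undersample_negatives(w1_pool, cases_w1, cases_w2, seed)
    removed_ids = {lp.patient_id for lp in removed}
    w2_cohort = [lp for lp in w2_all if lp.patient_id in removed_ids]
    logger.info(
        "wave 1: %d (cases %d); wave 2: %d (cases %d); ratio %.5f",
        len(w1_cohort), cases_w1, len(w2_cohort),
        sum(lp.y for lp in w2_cohort), cases_w1 / cases_w2,
    )
    return TwoWaveCohorts(w1_cohort, w2_cohort, cases_w1 / cases_w2, log)


# --------------------------------------------------------------------------
# summary table
# --------------------------------------------------------------------------


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage as printed in cohort summary tables."""
    if total == 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def summarize_cohort(
    cohort: list[LabeledPatient], top_k_codes: int = 10
) -> pd.DataFrame:
    """Demographics / top-code / prevalence summary of a labelled cohort,
    one row per (section, level): N, median and IQR for age, counts and
    percentages for categorical covariates and the outcome."""
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    rows = [("cohort", "N", n, np.nan, np.nan, np.nan)]
    ages = np.array([lp.patient.age for lp in cohort])
    q1, med, q3 = np.percentile(ages, [25, 50, 75])
    rows.append(("age", "median (IQR)", np.nan, med, q1, q3))
    for section, getter, levels in (
        ("sex", lambda lp: lp.patient.sex, ["F", "M"]),
        ("simd_decile", lambda lp: lp.patient.simd_decile, list(range(1, 11))),
        ("diabetes", lambda lp: lp.patient.diabetes, [0, 1]),
        ("incident_outcome", lambda lp: lp.y, [0, 1]),
    ):
        for level in levels:
            c = sum(1 for lp in cohort if getter(lp) == level)
            rows.append((section, str(level), c, percent(c, n), np.nan, np.nan))
    code_counts: dict[str, int] = {}
    for lp in cohort:
        seen = set()
        for e in lp.patient.events:
            key = f"{e.code_system}:{e.code}"
            if key not in seen:
                seen.add(key)
                code_counts[key] = code_counts.get(key, 0) + 1
    for key, c in sorted(code_counts.items(), key=lambda kv: (-kv[1], kv[0]))[
        :top_k_codes
    ]:
        rows.append(("top_codes", key, c, percent(c, n), np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["section", "level", "count", "value", "q1", "q3"]
    )


def cohort_frame(cohort: list[LabeledPatient]) -> pd.DataFrame:
    """cohort.csv layout: one row per patient with wave, label, exposures."""
    if not cohort:
        return pd.DataFrame()
    drug_names = sorted(cohort[0].exposure)
    rows = [
        [lp.patient_id, lp.wave_id, lp.y, lp.event_day]
        + [lp.exposure[d] for d in drug_names]
        for lp in cohort
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "wave_id", "Y", "event_day"]
        + [f"exposed_{d}" for d in drug_names],
    )
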