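"""Synthetic cohort simulator with known ground truth.

Generates patients whose statistical structure mirrors the study data
model: static covariates (age >= 40, sex, SIMD decile, diabetes), sparse
time-stamped BNF/ICD-10 code streams inside 180-day lookback windows,
confounded drug exposure (a logistic propensity in age, sex, deprivation,
diabetes and comorbidity burden), and a rare 180-day composite outcome
drawn additively on the probability scale:

    P(Y=1 | x, T) = clip( base_risk(x) + sum_d T_d * tau_d(x), 0, 1 )

so the configured per-drug effects tau_d are risk differences. The
simulator records the true propensity g*(x) and true ITE per drug so
downstream estimators can be validated against ground truth.

Seeding is counter-based: each patient's random stream is derived from
(master seed, patient index), so enlarging the cohort never reshuffles
earlier patients. Marginal calibration (propensity and base-risk
intercepts) uses a fixed internal reference sample for the same reason.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    BNF,
    ICD10,
    STUDY_DRUGS,
    DrugClass,
    EventRecord,
    GroundTruth,
    OutcomeDates,
    PatientRecord,
    WaveDefinition,
)

# --------------------------------------------------------------------------
# treatment effects on the risk-difference scale
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantEffect:
    """tau*(x) = value for every patient."""

    value: float

    def tau(self, age: float, sex: str, simd: int, diabetes: int) -> float:
        return self.value


@dataclass(frozen=True)
class AgeLinearEffect:
    """tau*(x) linear in age between 40 and 95 years."""

    at_age_40: float
    at_age_95: float

    def tau(self, age: float, sex: str, simd: int, diabetes: int) -> float:
        w = np.clip((age - 40.0) / 55.0, 0.0, 1.0)
        return self.at_age_40 + w * (self.at_age_95 - self.at_age_40)


@dataclass(frozen=True)
class TreatmentSpec:
    """One simulated drug: class, dispensable product codes, exposure target."""

    drug: DrugClass
    product_codes: tuple[str, ...]
    target_exposure: float
    effect: ConstantEffect | AgeLinearEffect


# --------------------------------------------------------------------------
# background code vocabulary
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CodeFrequency:
    code: str
    code_system: str
    rel_freq: float


# Background BNF stems follow the most commonly dispensed classes in a
# 40+ primary-care population (proton pump inhibitors, analgesics,
# bronchodilators, antiplatelets, antibiotics, SSRIs); ICD-10 categories
# follow common admission causes (cataract, respiratory infection, UTI,
# COPD, ischaemic heart disease, sepsis, breast neoplasm, chest pain,
# syncope). Admissions are roughly two orders of magnitude rarer than
# dispenses, matching the large "no admission" majority.
DEFAULT_VOCAB: tuple[CodeFrequency, ...] = (
    CodeFrequency("0103050P0", BNF, 0.60),
    CodeFrequency("0407010H0", BNF, 0.50),
    CodeFrequency("0301011R0", BNF, 0.21),
    CodeFrequency("0209000A0", BNF, 0.21),
    CodeFrequency("0501013B0", BNF, 0.19),
    CodeFrequency("0403030Q0", BNF, 0.20),
    CodeFrequency("H25", ICD10, 0.006),
    CodeFrequency("J22", ICD10, 0.004),
    CodeFrequency("N39", ICD10, 0.005),
    CodeFrequency("J44", ICD10, 0.003),
    CodeFrequency("I25", ICD10, 0.004),
    CodeFrequency("A41", ICD10, 0.003),
    CodeFrequency("C50", ICD10, 0.003),
    CodeFrequency("R07", ICD10, 0.004),
    CodeFrequency("R55", ICD10, 0.002),
)


def _default_treatments() -> tuple[TreatmentSpec, ...]:
    acei, bb, ccb, thz, statin = STUDY_DRUGS
    return (
        TreatmentSpec(acei, ("0205051R0", "0205051F0"), 0.195, ConstantEffect(0.005)),
        TreatmentSpec(bb, ("0204000H0", "0204000E0"), 0.211, ConstantEffect(-0.018)),
        TreatmentSpec(ccb, ("0206020A0", "0206020C0"), 0.184, ConstantEffect(-0.020)),
        TreatmentSpec(thz, ("0202010D0", "0202010F0"), 0.070, ConstantEffect(0.012)),
        TreatmentSpec(
            statin, ("0212000B0AA", "0212000Y0AA"), 0.326, ConstantEffect(0.010)
        ),
    )


# SIMD decile proportions and demographic rates of a West-of-Scotland
# urban 40+ population (deprived deciles over-represented).
SIMD_PROPS = np.array(
    [0.228, 0.146, 0.092, 0.081, 0.068, 0.065, 0.060, 0.074, 0.102, 0.085]
)
FEMALE_RATE = 0.562
DIABETES_RATE = 0.081
_AGE_BETA = (1.2, 2.0)  # age = 40 + 55 * Beta(a, b)

_AGE_MEAN = 40.0 + 55.0 * _AGE_BETA[0] / (_AGE_BETA[0] + _AGE_BETA[1])
_AGE_SD = 55.0 * np.sqrt(
    _AGE_BETA[0]
    * _AGE_BETA[1]
    / ((_AGE_BETA[0] + _AGE_BETA[1]) ** 2 * (sum(_AGE_BETA) + 1))
)

# propensity coefficients on standardised covariates, scaled by
# confounding_strength: older, male, diabetic, comorbid patients are
# more likely to be dispensed a study drug
_PROP_BETA = {"age": 0.9, "male": 0.2, "simd": -0.10, "diabetes": 0.8, "comorb": 0.4}

# base-risk coefficients (probability scale, bounded terms)
_RISK_BETA = {"age": 0.018, "diabetes": 0.012, "comorb": 0.010, "depriv": 0.005}

_CALIBRATION_SEED = 714025  # fixed: calibration must not depend on n_patients
_CALIBRATION_N = 20000


@dataclass
class SimulationConfig:
    n_patients: int
    seed: int
    wave_count: int = 2
    lookback_days: int = 180
    followup_days: int = 180
    base_event_rate: float = 2.5
    vocab_spec: tuple[CodeFrequency, ...] = DEFAULT_VOCAB
    treatments: tuple[TreatmentSpec, ...] = field(default_factory=_default_treatments)
    confounding_strength: float = 1.0
    outcome_base_prevalence: float = 0.095
    propensity_noise_sd: float = 0.2
    risk_scale: str = "probability"  # or "logit"
    clip_tolerance: float = 1e-9
    persistence_logit: float = 2.5  # wave-2 continuation boost for wave-1 users
    start_date: dt.date = dt.date(2019, 10, 1)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0.0 < self.outcome_base_prevalence < 1.0):
            raise ValueError("outcome_base_prevalence must lie in (0, 1)")
        if self.lookback_days <= 0 or self.followup_days <= 0:
            raise ValueError("window lengths must be positive")
        if self.wave_count not in (1, 2):
            raise ValueError("wave_count must be 1 or 2")
        if self.confounding_strength < 0:
            raise ValueError("confounding_strength must be >= 0")
        if self.risk_scale not in ("probability", "logit"):
            raise ValueError("risk_scale must be 'probability' or 'logit'")

    def waves(self) -> list[WaveDefinition]:
        # wave boundaries are 6-calendar-month steps (as in the study
        # calendar: Oct 1 -> Apr 1 -> Oct 1), so lookback windows are 182-184
        # days while the follow-up assessment window stays followup_days long
        out = []
        for w in range(self.wave_count):
            lb_start = _add_months(self.start_date, 6 * w)
            lb_end = _add_months(self.start_date, 6 * (w + 1))
            out.append(WaveDefinition(w + 1, lb_start, lb_end, self.followup_days))
        return out


# --------------------------------------------------------------------------


def _add_months(d: dt.date, months: int) -> dt.date:
    m = d.month - 1 + months
    return d.replace(year=d.year + m // 12, month=m % 12 + 1)


def _standardise(age, male, simd, diabetes, n_icd):
    return {
        "age": (age - _AGE_MEAN) / _AGE_SD,
        "male": male,
        "simd": (simd - 5.5) / 2.87,
        "diabetes": diabetes,
        "comorb": np.log1p(n_icd),
    }


def _propensity_logit_lp(z, strength):
    return strength * sum(_PROP_BETA[k] * z[k] for k in _PROP_BETA)


def _risk_lp(z):
    return (
        _RISK_BETA["age"] * np.tanh(z["age"])
        + _RISK_BETA["diabetes"] * z["diabetes"]
        + _RISK_BETA["comorb"] * np.tanh(z["comorb"])
        + _RISK_BETA["depriv"] * (-np.tanh(z["simd"]))
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def _reference_sample(cfg: SimulationConfig):
    """Fixed covariate sample used only to calibrate intercepts."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    n = _CALIBRATION_N
    age = 40.0 + 55.0 * rng.beta(*_AGE_BETA, size=n)
    male = (rng.random(n) >= FEMALE_RATE).astype(float)
    simd = rng.choice(np.arange(1, 11), size=n, p=SIMD_PROPS / SIMD_PROPS.sum())
    diabetes = (rng.random(n) < DIABETES_RATE).astype(float)
    icd_rate = cfg.base_event_rate * _icd_fraction(cfg.vocab_spec)
    n_icd = rng.poisson(icd_rate, size=n)
    noise = rng.normal(0.0, cfg.propensity_noise_sd, size=n)
    return _standardise(age, male, simd, diabetes, n_icd), noise


def _icd_fraction(vocab):
    tot = sum(c.rel_freq for c in vocab)
    return sum(c.rel_freq for c in vocab if c.code_system == ICD10) / tot


def _solve_intercept(fn, target, lo=-20.0, hi=20.0, iters=60):
    """Bisection for a on mean(fn(a)) = target; fn monotone increasing in a."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_intercepts(cfg: SimulationConfig):
    """Propensity intercept per drug and base-risk intercept, calibrated on
    the fixed reference sample so results do not depend on n_patients."""
    z, noise = _reference_sample(cfg)
    prop_lp = _propensity_logit_lp(z, cfg.confounding_strength) + noise
    alphas = {
        t.drug.name: _solve_intercept(
            lambda a, lp=prop_lp: _sigmoid(a + lp).mean(), t.target_exposure
        )
        for t in cfg.treatments
    }
    risk_lp = _risk_lp(z)
    if cfg.risk_scale == "probability":
        a0 = _solve_intercept(
            lambda a: np.clip(a + risk_lp, 0, 1).mean(), cfg.outcome_base_prevalence
        )
    else:
        # logit-additive alternative: amplify the bounded lp so covariates
        # retain comparable leverage on the logit scale
        a0 = _solve_intercept(
            lambda a: _sigmoid(a + risk_lp * 10.0).mean(),
            cfg.outcome_base_prevalence,
        )
    return alphas, a0


def _base_risk(a0, z, risk_scale):
    lp = _risk_lp(z)
    if risk_scale == "probability":
        return a0 + lp
    return _sigmoid(a0 + lp * 10.0)


# --------------------------------------------------------------------------


def simulate_cohort(cfg: SimulationConfig):
    """Generate the cohort.

    Returns ``(patients, ground_truths)`` where ground truth rows exist for
    every patient in wave 1 and, in two-wave mode, for each wave-1 negative
    in wave 2 (the study design assesses wave-2 outcomes only for patients
    without a wave-1 event).
    """
    waves = cfg.waves()
    alphas, a0 = calibrate_intercepts(cfg)
    drug_names = [t.drug.name for t in cfg.treatments]

    vocab = list(cfg.vocab_spec)
    freqs = np.array([c.rel_freq for c in vocab], dtype=float)
    freqs = freqs / freqs.sum()

    patients: list[PatientRecord] = []
    truths: list[GroundTruth] = []
    preclip_min, preclip_max = np.inf, -np.inf

    for i in range(cfg.n_patients):
        rng = np.random.default_rng([cfg.seed, i])
        age = 40.0 + 55.0 * rng.beta(*_AGE_BETA)
        sex = "F" if rng.random() < FEMALE_RATE else "M"
        simd = int(rng.choice(np.arange(1, 11), p=SIMD_PROPS / SIMD_PROPS.sum()))
        diabetes = int(rng.random() < DIABETES_RATE)
        patient = PatientRecord(i, age, sex, simd, diabetes)
        prev_treated: dict[str, int] = {d: 0 for d in drug_names}
        had_event = False

        for wave in waves:
            if wave.wave_id > 1 and had_event:
                # study design: wave-2 outcomes assessed only for wave-1
                # negatives; continue their dispensing stream anyway
                pass
            # background events in this wave's lookback
            window_days = (wave.lookback_end - wave.lookback_start).days
            n_bg = rng.poisson(cfg.base_event_rate)
            if n_bg:
                codes = rng.choice(len(vocab), size=n_bg, p=freqs)
                offsets = rng.integers(0, window_days, size=n_bg)
                for ci, off in zip(codes, offsets):
                    c = vocab[ci]
                    patient.events.append(
                        EventRecord(
                            i,
                            wave.lookback_start + dt.timedelta(days=int(off)),
                            c.code,
                            c.code_system,
                        )
                    )
                n_icd = int(sum(1 for ci in codes if vocab[ci].code_system == ICD10))
            else:
                n_icd = 0

            z = _standardise(age, 1.0 if sex == "M" else 0.0, simd, diabetes, n_icd)
            noise = rng.normal(0.0, cfg.propensity_noise_sd)
            lp = _propensity_logit_lp(z, cfg.confounding_strength) + noise

            g, T = {}, {}
            for t in cfg.treatments:
                logit = alphas[t.drug.name] + lp
                if wave.wave_id > 1:
                    # dispensing persistence: wave-1 users tend to continue
                    logit += cfg.persistence_logit * (
                        prev_treated[t.drug.name] - t.target_exposure
                    )
                g[t.drug.name] = float(_sigmoid(logit))
                T[t.drug.name] = int(rng.random() < g[t.drug.name])
                if T[t.drug.name]:
                    n_disp = 1 + int(min(rng.poisson(1.2), 4))
                    days = rng.integers(0, window_days, size=n_disp)
                    for dday in days:
                        code = t.product_codes[int(rng.integers(len(t.product_codes)))]
                        patient.events.append(
                            EventRecord(
                                i,
                                wave.lookback_start + dt.timedelta(days=int(dday)),
                                code,
                                BNF,
                            )
                        )
            prev_treated = T

            if had_event:
                continue  # no further outcome assessment after the first event

            base = _base_risk(a0, z, cfg.risk_scale)
            total = base + sum(
                T[t.drug.name] * t.effect.tau(age, sex, simd, diabetes)
                for t in cfg.treatments
            )
            p_tr, p_ct, ite = {}, {}, {}
            for t in cfg.treatments:
                tau = t.effect.tau(age, sex, simd, diabetes)
                with_d = total + (1 - T[t.drug.name]) * tau
                without_d = total - T[t.drug.name] * tau
                preclip_min = min(preclip_min, with_d, without_d)
                preclip_max = max(preclip_max, with_d, without_d)
                p_tr[t.drug.name] = float(np.clip(with_d, 0, 1))
                p_ct[t.drug.name] = float(np.clip(without_d, 0, 1))
                ite[t.drug.name] = p_tr[t.drug.name] - p_ct[t.drug.name]
            truths.append(
                GroundTruth(i, wave.wave_id, dict(g), ite, p_tr, p_ct)
            )
            p_outcome = float(np.clip(total, 0, 1))
            preclip_min = min(preclip_min, total)
            preclip_max = max(preclip_max, total)
            if rng.random() < p_outcome:
                had_event = True
                day = int(rng.integers(0, cfg.followup_days))
                test_date = wave.followup_start + dt.timedelta(days=day)
                patient.outcome.test_date = test_date
                if rng.random() < 0.22:
                    patient.outcome.hosp_date = test_date + dt.timedelta(
                        days=int(rng.integers(0, 10))
                    )
                if rng.random() < 0.03:
                    patient.outcome.death_date = test_date + dt.timedelta(
                        days=int(rng.integers(5, 25))
                    )

        patient.sort_events()
        patients.append(patient)

    if preclip_min < -cfg.clip_tolerance or preclip_max > 1 + cfg.clip_tolerance:
        raise ValueError(
            "mis-specified scenario: outcome probabilities leave [0,1] before "
            f"clipping (range [{preclip_min:.4f}, {preclip_max:.4f}])"
        )
    return patients, truths


# --------------------------------------------------------------------------
# named scenarios used throughout validation
# --------------------------------------------------------------------------


def default_config(n_patients: int, seed: int) -> SimulationConfig:
    """Two waves, five drug classes, small realistic effects, 9.5% prevalence."""
    return SimulationConfig(n_patients=n_patients, seed=seed)


def null_scenario(
    n_patients: int, seed: int, confounding_strength: float = 1.0
) -> SimulationConfig:
    """tau* = 0 for every drug; single analysis wave."""
    treatments = tuple(
        dataclasses.replace(t, effect=ConstantEffect(0.0))
        for t in _default_treatments()
    )
    return SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        wave_count=1,
        treatments=treatments,
        confounding_strength=confounding_strength,
    )


def constant_effect_scenario(
    n_patients: int, seed: int, tau: float = -0.10
) -> SimulationConfig:
    """A single drug with a constant risk difference; higher base prevalence
    (0.30) so a double-digit risk difference never clips."""
    bb = _default_treatments()[1]
    return SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        wave_count=1,
        treatments=(dataclasses.replace(bb, effect=ConstantEffect(tau)),),
        outcome_base_prevalence=0.30,
    )


def heterogeneous_age_scenario(n_patients: int, seed: int) -> SimulationConfig:
    """A single drug whose effect declines linearly with age (protective in
    the elderly, mildly harmful in the youngest eligible patients)."""
    bb = _default_treatments()[1]
    return SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        wave_count=1,
        treatments=(
            dataclasses.replace(bb, effect=AgeLinearEffect(0.05, -0.20)),
        ),
        outcome_base_prevalence=0.30,
    )


# --------------------------------------------------------------------------
# CSV interfaces
# --------------------------------------------------------------------------


def write_cohort_csvs(patients, truths, outdir, ground_truth=True) -> dict[str, Path]:
    """Write events.csv, demographics.csv, outcomes.csv (+ ground_truth.csv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev = pd.DataFrame(
        [
            (e.patient_id, e.event_date.isoformat(), e.code, e.code_system)
            for p in patients
            for e in p.events
        ],
        columns=["patient_id", "event_date", "code", "code_system"],
    )
    demo = pd.DataFrame(
        [
            (p.patient_id, p.age, p.sex, p.simd_decile, p.diabetes)
            for p in patients
        ],
        columns=["patient_id", "age", "sex", "simd_decile", "diabetes"],
    )
    outc = pd.DataFrame(
        [
            (
                p.patient_id,
                p.outcome.test_date.isoformat() if p.outcome.test_date else "",
                p.outcome.hosp_date.isoformat() if p.outcome.hosp_date else "",
                p.outcome.death_date.isoformat() if p.outcome.death_date else "",
            )
            for p in patients
        ],
        columns=["patient_id", "test_date", "hosp_date", "death_date"],
    )
    paths = {}
    for name, df in (("events", ev), ("demographics", demo), ("outcomes", outc)):
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    if ground_truth:
        gt = pd.DataFrame(
            [
                (
                    t.patient_id,
                    t.wave_id,
                    drug,
                    t.true_propensity[drug],
                    t.true_ite[drug],
                    t.true_outcome_prob_treated[drug],
                    t.true_outcome_prob_control[drug],
                )
                for t in truths
                for drug in t.true_propensity
            ],
            columns=[
                "patient_id", "wave_id", "drug", "true_propensity", "true_ite",
                "true_outcome_prob_treated", "true_outcome_prob_control",
            ],
        )
        paths["ground_truth"] = outdir / "ground_truth.csv"
        gt.to_csv(paths["ground_truth"], index=False)
    return paths


def read_cohort_csvs(indir) -> list[PatientRecord]:
    """Load patients from the three-file CSV schema (same schema accepted
    for real extracts)."""
    indir = Path(indir)
    demo_path = indir / "demographics.csv"
    for required in ("events.csv", "demographics.csv", "outcomes.csv"):
        if not (indir / required).exists():
            raise FileNotFoundError(f"missing input table: {indir / required}")
    demo = pd.read_csv(demo_path)
    events = pd.read_csv(indir / "events.csv")
    outc = pd.read_csv(indir / "outcomes.csv")

    def _parse(x):
        return dt.date.fromisoformat(x) if isinstance(x, str) and x else None

    patients: dict[int, PatientRecord] = {}
    for row in demo.itertuples(index=False):
        patients[int(row.patient_id)] = PatientRecord(
            int(row.patient_id),
            float(row.age) if pd.notna(row.age) else None,
            row.sex if isinstance(row.sex, str) else None,
            int(row.simd_decile) if pd.notna(row.simd_decile) else None,
            int(row.diabetes) if pd.notna(row.diabetes) else None,
        )
    for row in events.itertuples(index=False):
        pid = int(row.patient_id)
        if pid in patients:
            patients[pid].events.append(
                EventRecord(
                    pid, dt.date.fromisoformat(row.event_date), row.code,
                    row.code_system,
                )
            )
    for row in outc.itertuples(index=False):
        pid = int(row.patient_id)
        if pid in patients:
            patients[pid].outcome = OutcomeDates(
                _parse(row.test_date), _parse(row.hosp_date), _parse(row.death_date)
            )
    ordered = [patients[k] for k in sorted(patients)]
    for p in ordered:
        p.sort_events()
    return ordered
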