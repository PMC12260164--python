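"""Tokenisation of 180-day lookback event streams for the sequence models.

Codes are truncated to a clinically meaningful granularity (BNF to the
7-character chemical-substance stem, ICD-10 to the 3-character category),
mapped through a vocabulary built on training data only, and laid out as
fixed-length padded sequences of (token id, day offset) pairs together
with a standardised static covariate vector.

When encoding inputs for a drug's causal models, every event carrying
that drug's BNF prefix is removed first (leakage guard): otherwise the
treatment indicator would be trivially readable from the sequence and the
counterfactual surfaces would collapse onto the factual arm.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import BNF, LabeledPatient, PatientRecord, WaveDefinition

PAD, UNK, CLS = "<pad>", "<unk>", "<cls>"
PAD_ID, UNK_ID, CLS_ID = 0, 1, 2
N_RESERVED = 3


def truncate_code(code: str, code_system: str, bnf_chars: int = 7,
                  icd_chars: int = 3) -> str:
    return code[:bnf_chars] if code_system == BNF else code[:icd_chars]


@dataclass
class Vocabulary:
    """token -> id map with reserved PAD/UNK/CLS indices."""

    tokens: list[str]
    counts: list[int]
    code_systems: list[str]
    bnf_chars: int = 7
    icd_chars: int = 3
    token_to_id: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.token_to_id = {
            tok: i + N_RESERVED for i, tok in enumerate(self.tokens)
        }

    def __len__(self) -> int:
        return len(self.tokens) + N_RESERVED

    def lookup(self, code: str, code_system: str) -> int:
        tok = truncate_code(code, code_system, self.bnf_chars, self.icd_chars)
        return self.token_to_id.get(tok, UNK_ID)

    def decode(self, token_id: int) -> str:
        if token_id < N_RESERVED:
            return (PAD, UNK, CLS)[token_id]
        return self.tokens[token_id - N_RESERVED]

    def to_json(self, path) -> None:
        payload = [
            {"token": t, "id": i + N_RESERVED, "count": c, "code_system": s}
            for i, (t, c, s) in enumerate(
                zip(self.tokens, self.counts, self.code_systems)
            )
        ]
        Path(path).write_text(
            json.dumps(
                {"bnf_chars": self.bnf_chars, "icd_chars": self.icd_chars,
                 "tokens": payload},
                indent=0, sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        raw = json.loads(Path(path).read_text())
        toks = sorted(raw["tokens"], key=lambda r: r["id"])
        return cls(
            [r["token"] for r in toks],
            [r["count"] for r in toks],
            [r["code_system"] for r in toks],
            raw["bnf_chars"],
            raw["icd_chars"],
        )


def build_vocabulary(
    patients,
    min_count: int = 1,
    bnf_chars: int = 7,
    icd_chars: int = 3,
    wave: WaveDefinition | None = None,
) -> Vocabulary:
    """Count truncated codes over training patients and index them by
    descending count (ties broken lexicographically). Codes below
    ``min_count`` fall through to UNK at lookup time."""
    counter: Counter = Counter()
    systems: dict[str, str] = {}
    for lp in patients:
        p = lp.patient if isinstance(lp, LabeledPatient) else lp
        for e in p.events:
            if wave is not None and not wave.in_lookback(e.event_date):
                continue
            tok = truncate_code(e.code, e.code_system, bnf_chars, icd_chars)
            counter[tok] += 1
            systems[tok] = e.code_system
    kept = sorted(
        ((t, c) for t, c in counter.items() if c >= min_count),
        key=lambda tc: (-tc[1], tc[0]),
    )
    return Vocabulary(
        [t for t, _ in kept],
        [c for _, c in kept],
        [systems[t] for t, _ in kept],
        bnf_chars,
        icd_chars,
    )


@dataclass
class EncodedPatient:
    """Model input for one patient: padded token/day arrays + statics."""

    patient_id: int
    token_ids: np.ndarray  # (max_len,) int32
    day_offsets: np.ndarray  # (max_len,) int32, from lookback_start
    padding_mask: np.ndarray  # (max_len,) bool, True on real tokens
    static_features: np.ndarray  # (n_static,) float32


class StaticScaler:
    """Standardises age on training statistics; sex one-hot, SIMD decile
    as integer, diabetes flag pass through."""

    N_FEATURES = 5

    def __init__(self) -> None:
        self.age_mean = 0.0
        self.age_sd = 1.0

    def fit(self, patients) -> "StaticScaler":
        ages = [
            (lp.patient if isinstance(lp, LabeledPatient) else lp).age
            for lp in patients
        ]
        self.age_mean = float(np.mean(ages))
        self.age_sd = float(np.std(ages)) or 1.0
        return self

    def transform(self, p: PatientRecord) -> np.ndarray:
        return np.array(
            [
                (p.age - self.age_mean) / self.age_sd,
                1.0 if p.sex == "F" else 0.0,
                1.0 if p.sex == "M" else 0.0,
                float(p.simd_decile),
                float(p.diabetes),
            ],
            dtype=np.float32,
        )


def encode_patient(
    patient: PatientRecord,
    wave: WaveDefinition,
    vocab: Vocabulary,
    max_len: int,
    scaler: StaticScaler,
    exclude_prefixes: tuple[str, ...] = (),
) -> EncodedPatient:
    """Encode one patient's lookback window.

    Events are sorted by (date, BNF before ICD-10, code); when more than
    ``max_len`` remain the most recent are kept. A patient with no
    lookback events yields an all-PAD sequence with valid statics.
    """
    events = [
        e
        for e in patient.events
        if wave.in_lookback(e.event_date)
        and not (
            e.code_system == BNF
            and any(e.code.startswith(pref) for pref in exclude_prefixes)
        )
    ]
    # PatientRecord keeps events sorted; enforce anyway for raw inputs
    events.sort(key=lambda e: (e.event_date,
                               0 if e.code_system == BNF else 1, e.code))
    if len(events) > max_len:
        events = events[-max_len:]
    ids = np.full(max_len, PAD_ID, dtype=np.int32)
    days = np.zeros(max_len, dtype=np.int32)
    mask = np.zeros(max_len, dtype=bool)
    for j, e in enumerate(events):
        ids[j] = vocab.lookup(e.code, e.code_system)
        days[j] = (e.event_date - wave.lookback_start).days
        mask[j] = True
    return EncodedPatient(
        patient.patient_id, ids, days, mask, scaler.transform(patient)
    )


@dataclass
class EncodedCohort:
    """Stacked model inputs for a set of patients (row-aligned arrays)."""

    patient_ids: np.ndarray  # (N,)
    token_ids: np.ndarray  # (N, max_len)
    day_offsets: np.ndarray
    padding_mask: np.ndarray
    static_features: np.ndarray
    vocab_size: int

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, idx) -> "EncodedCohort":
        return EncodedCohort(
            self.patient_ids[idx],
            self.token_ids[idx],
            self.day_offsets[idx],
            self.padding_mask[idx],
            self.static_features[idx],
            self.vocab_size,
        )

    def bag_of_tokens(self) -> np.ndarray:
        """(N, vocab_size) token count matrix for the tabular baselines."""
        n, v = len(self), self.vocab_size
        out = np.zeros((n, v), dtype=np.float32)
        rows = np.repeat(np.arange(n), self.token_ids.shape[1])
        ids = self.token_ids.ravel()
        real = self.padding_mask.ravel()
        np.add.at(out, (rows[real], ids[real]), 1.0)
        return out


def encode_cohort(
    labeled,
    wave: WaveDefinition,
    vocab: Vocabulary,
    max_len: int,
    scaler: StaticScaler,
    exclude_prefixes: tuple[str, ...] = (),
) -> EncodedCohort:
    encoded = [
        encode_patient(
            lp.patient if isinstance(lp, LabeledPatient) else lp,
            wave, vocab, max_len, scaler, exclude_prefixes,
        )
        for lp in labeled
    ]
    if not encoded:
        raise ValueError("cannot encode an empty cohort")
    return EncodedCohort(
        np.array([e.patient_id for e in encoded]),
        np.stack([e.token_ids for e in encoded]),
        np.stack([e.day_offsets for e in encoded]),
        np.stack([e.padding_mask for e in encoded]),
        np.stack([e.static_features for e in encoded]),
        len(vocab),
    )
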