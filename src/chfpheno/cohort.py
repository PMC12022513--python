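"""Screening-group assignment and stratified, keyword-filtered note sampling.

Patients are screened into four groups by the presence of CHF-related
diagnosis codes (ICD-9 stem 428, ICD-10 stem I50) and CHF-related medications
(nine generic drugs): ``ICD+/MED+``, ``ICD+/MED-``, ``ICD-/MED+``,
``ICD-/MED-``.  The groups enrich an annotation sample for likely-positive
notes; the modelling sample is then drawn per group from notes that mention at
least one screening keyword.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime
from enum import Enum

import numpy as np

__all__ = [
    "ScreeningGroup",
    "CodedEvent",
    "NoteDocument",
    "PatientRecord",
    "ScreeningCriteria",
    "DEFAULT_ICD_STEMS",
    "DEFAULT_MEDICATIONS",
    "DEFAULT_KEYWORD_FILTER",
    "normalize_code",
    "normalize_medication",
    "assign_group",
    "sample_notes",
]


class ScreeningGroup(str, Enum):
    """Four-way stratum from diagnosis-code and medication screening."""

    ICD_POS_MED_POS = "ICD+/MED+"
    ICD_POS_MED_NEG = "ICD+/MED-"
    ICD_NEG_MED_POS = "ICD-/MED+"
    ICD_NEG_MED_NEG = "ICD-/MED-"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_flags(cls, icd_pos: bool, med_pos: bool) -> "ScreeningGroup":
        return {
            (True, True): cls.ICD_POS_MED_POS,
            (True, False): cls.ICD_POS_MED_NEG,
            (False, True): cls.ICD_NEG_MED_POS,
            (False, False): cls.ICD_NEG_MED_NEG,
        }[(icd_pos, med_pos)]


DEFAULT_ICD_STEMS: tuple[str, ...] = ("428", "I50")

#: Generic names of the nine screening medications (ACE inhibitors, loop and
#: thiazide diuretics, beta/calcium-channel blockers, a vasodilator, and
#: omeprazole, which co-occurs with CHF polypharmacy).
DEFAULT_MEDICATIONS: tuple[str, ...] = (
    "lisinopril",
    "furosemide",
    "bumetanide",
    "propranolol",
    "amlodipine",
    "hydrochlorothiazide",
    "omeprazole",
    "isosorbide mononitrate",
    "enalapril",
)

DEFAULT_KEYWORD_FILTER: tuple[str, ...] = ("heart", "chf", "congestive")


def _parse_date(value) -> _date:
    if isinstance(value, _date) and not isinstance(value, datetime):
        return value
    if isinstance(value, datetime):
        return value.date()
    try:
        return _date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"unparseable date {value!r}") from exc


@dataclass(frozen=True)
class CodedEvent:
    """One dated structured event: an ICD code or a prescribed medication."""

    patient_id: str
    date: _date
    kind: str  # "icd" | "med"
    value: str

    def __post_init__(self):
        object.__setattr__(self, "date", _parse_date(self.date))
        if self.kind not in ("icd", "med"):
            raise ValueError(f"event kind must be 'icd' or 'med', got {self.kind!r}")
        if not str(self.value).strip():
            raise ValueError("event value must be non-empty")


@dataclass(frozen=True)
class NoteDocument:
    """One clinical note with its authoring site and date."""

    note_id: str
    patient_id: str
    site: str
    date: _date
    text: str

    def __post_init__(self):
        object.__setattr__(self, "date", _parse_date(self.date))
        if not self.text:
            raise ValueError(f"note {self.note_id} has empty text")


@dataclass
class PatientRecord:
    """All notes and coded events for one patient."""

    patient_id: str
    notes: list[NoteDocument] = field(default_factory=list)
    events: list[CodedEvent] = field(default_factory=list)

    def __post_init__(self):
        for n in self.notes:
            if n.patient_id != self.patient_id:
                raise ValueError(
                    f"note {n.note_id} belongs to {n.patient_id}, not {self.patient_id}"
                )
        for e in self.events:
            if e.patient_id != self.patient_id:
                raise ValueError(f"event for {e.patient_id} attached to {self.patient_id}")


@dataclass(frozen=True)
class ScreeningCriteria:
    """Code stems and generic medication names that define the four groups."""

    icd_stems: tuple[str, ...] = DEFAULT_ICD_STEMS
    medications: tuple[str, ...] = DEFAULT_MEDICATIONS

    def __post_init__(self):
        if not self.icd_stems or not self.medications:
            raise ValueError("icd_stems and medications must be non-empty")
        norm = tuple(normalize_code(s) for s in self.icd_stems)
        object.__setattr__(self, "icd_stems", norm)
        object.__setattr__(
            self, "medications", tuple(" ".join(m.lower().split()) for m in self.medications)
        )


def normalize_code(code: str) -> str:
    """Canonical ICD form: uppercase, dots and whitespace removed.

    EHR exports disagree on dotting ("I50.32" vs "I509"); stems are matched on
    the dotless form.
    """
    return re.sub(r"[.\s]", "", str(code)).upper()


_DOSE_TOKEN_RE = re.compile(
    r"^\d+(\.\d+)?(mg|mcg|g|ml|meq|units?|iu|%)?$|^(mg|mcg|ml|meq|iu)$"
)
_ROUTE_TOKENS = frozenset(
    {
        "po", "iv", "im", "sc", "sl", "oral", "tablet", "tab", "tabs", "cap",
        "capsule", "caps", "solution", "daily", "bid", "tid", "qid", "qd",
        "qhs", "prn", "er", "xl", "sr", "hcl",
    }
)


def normalize_medication(value: str) -> str:
    """Reduce a prescription string to its generic name.

    Lowercases and drops dose, unit, and route tokens, so
    ``"FUROSEMIDE 40MG PO daily"`` becomes ``"furosemide"``.  Whole tokens
    only — the generic name itself is never truncated.
    """
    tokens = re.split(r"[^a-z0-9.%]+", str(value).lower())
    kept = [
        t
        for t in tokens
        if t and not _DOSE_TOKEN_RE.match(t) and t not in _ROUTE_TOKENS
    ]
    return " ".join(kept)


def assign_group(
    record: PatientRecord, criteria: ScreeningCriteria | None = None
) -> ScreeningGroup:
    """Screen one patient into a group using their entire event history.

    ICD+ iff any diagnosis code, after dot/whitespace normalization, starts
    with a criteria stem.  MED+ iff any medication event value equals a
    criteria generic name exactly (case- and whitespace-insensitive).  Raw
    prescription strings carrying dose text fail that exact match and should
    be passed through :func:`normalize_medication` first (the bundled loaders
    do this).  A patient with no events is ICD-/MED-.
    """
    criteria = criteria or ScreeningCriteria()
    icd_pos = False
    med_pos = False
    meds = set(criteria.medications)
    for ev in record.events:
        if ev.kind == "icd":
            code = normalize_code(ev.value)
            if any(code.startswith(stem) for stem in criteria.icd_stems):
                icd_pos = True
        else:
            if " ".join(ev.value.lower().split()) in meds:
                med_pos = True
    return ScreeningGroup.from_flags(icd_pos, med_pos)


def sample_notes(
    records: list[PatientRecord],
    quotas: dict[ScreeningGroup, int],
    keyword_filter: list[str] = DEFAULT_KEYWORD_FILTER,
    seed: int = 0,
    criteria: ScreeningCriteria | None = None,
) -> list[NoteDocument]:
    """Draw the stratified, keyword-filtered modelling sample.

    Eligible notes contain at least one filter phrase (case-insensitive
    substring).  From each group's eligible pool, ``min(quota, pool)`` notes
    are drawn without replacement; a shortfall emits a warning and returns the
    partial sample.  Deterministic for a fixed seed.
    """
    if not keyword_filter:
        raise ValueError("keyword_filter must be non-empty")
    if any(q < 0 for q in quotas.values()):
        raise ValueError("quotas must be nonnegative")
    criteria = criteria or ScreeningCriteria()
    phrases = [p.lower() for p in keyword_filter]

    pools: dict[ScreeningGroup, list[NoteDocument]] = {g: [] for g in ScreeningGroup}
    for rec in records:
        group = assign_group(rec, criteria)
        for note in rec.notes:
            low = note.text.lower()
            if any(p in low for p in phrases):
                pools[group].append(note)

    rng = np.random.default_rng(seed)
    sampled: list[NoteDocument] = []
    for group in ScreeningGroup:  # fixed iteration order for determinism
        quota = int(quotas.get(group, 0))
        if quota == 0:
            continue
        pool = sorted(pools[group], key=lambda n: n.note_id)
        if quota > len(pool):
            warnings.warn(
                f"group {group.value}: quota {quota} exceeds eligible pool "
                f"({len(pool)}); returning the whole pool",
                stacklevel=2,
            )
            quota = len(pool)
        idx = rng.choice(len(pool), size=quota, replace=False) if pool else []
        sampled.extend(pool[i] for i in sorted(idx))
    return sampled
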