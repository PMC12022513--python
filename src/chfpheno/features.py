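"""Feature construction: lexicon phrase counts, ICD-stem and medication counts.

Each labeled note becomes one row.  Text features are raw occurrence counts
of normalized lexicon phrases in the note (a negated mention such as
"no chf" increments both the "no chf" and "chf" columns; the classifier
weighs them against each other).  Structured features count the patient's
ICD events per screening stem and medication events per generic name inside
a closed +/-18-calendar-month window around the note date.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from ._text import normalize_text, sentence_token_lists
from .cohort import (
    DEFAULT_ICD_STEMS,
    DEFAULT_MEDICATIONS,
    CodedEvent,
    NoteDocument,
    PatientRecord,
    normalize_code,
)
from .keywords import KeywordLexicon

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "normalize_text",
    "count_phrase",
    "add_months",
    "count_events",
    "build_matrix",
    "MODALITIES",
]

MODALITIES = ("notes", "icd", "med")


@dataclass
class FeatureSpec:
    """What goes into a feature vector and how text is normalized."""

    lexicon: KeywordLexicon = field(default_factory=KeywordLexicon)
    icd_stems: tuple[str, ...] = DEFAULT_ICD_STEMS
    medications: tuple[str, ...] = DEFAULT_MEDICATIONS
    event_window_months: int = 18  # applied both directions, closed interval
    text_normalizer: str = "both"  # "stem" | "lemma" | "both"

    def __post_init__(self):
        if self.event_window_months <= 0:
            raise ValueError("event_window_months must be > 0")
        self.icd_stems = tuple(normalize_code(s) for s in self.icd_stems)
        self.medications = tuple(" ".join(m.lower().split()) for m in self.medications)

    def phrase_columns(self) -> list[tuple[str, ...]]:
        """Lexicon phrases in the normalized token space (deduplicated)."""
        return self.lexicon.normalized_phrases(self.text_normalizer)


@dataclass
class FeatureMatrix:
    """Dense count matrix plus column provenance; rows follow note order."""

    frame: pd.DataFrame  # index: note_id
    provenance: dict[str, dict]  # column -> {"modality": ..., "kind": ...}
    labels: pd.Series | None = None

    @property
    def note_ids(self) -> list[str]:
        return list(self.frame.index)

    def columns_for(self, modalities) -> list[str]:
        wanted = set(modalities)
        return [c for c in self.frame.columns if self.provenance[c]["modality"] in wanted]

    def restrict(self, modalities) -> "FeatureMatrix":
        cols = self.columns_for(modalities)
        return FeatureMatrix(
            frame=self.frame[cols],
            provenance={c: self.provenance[c] for c in cols},
            labels=self.labels,
        )

    def to_csv(self, path, sidecar_path=None) -> None:
        self.frame.to_csv(path)
        if sidecar_path is not None:
            import json

            with open(sidecar_path, "w") as fh:
                json.dump(self.provenance, fh, indent=1)


def count_phrase(tokens, phrase_tokens) -> int:
    """Overlapping occurrences of a normalized phrase in a token sequence."""
    phrase = tuple(phrase_tokens)
    if not phrase:
        return 0
    toks = tuple(tokens)
    k = len(phrase)
    return sum(1 for i in range(len(toks) - k + 1) if toks[i : i + k] == phrase)


def add_months(day: _date, months: int) -> _date:
    """Calendar-month shift, clamping to the target month's last day."""
    month_index = day.month - 1 + months
    year = day.year + month_index // 12
    month = month_index % 12 + 1
    dom = min(day.day, calendar.monthrange(year, month)[1])
    return _date(year, month, dom)


def count_events(
    events: list[CodedEvent], note_date: _date, spec: FeatureSpec
) -> dict[str, int]:
    """Per-stem and per-medication event counts in the closed window.

    An event on exactly ``note_date +/- event_window_months`` (calendar
    arithmetic, month-end clamped) is counted.  Each dated event row counts
    once; no encounter de-duplication.
    """
    lo = add_months(note_date, -spec.event_window_months)
    hi = add_months(note_date, spec.event_window_months)
    counts: dict[str, int] = {f"icd:{s}": 0 for s in spec.icd_stems}
    counts.update({f"med:{m}": 0 for m in spec.medications})
    meds = set(spec.medications)
    for ev in events:
        if not (lo <= ev.date <= hi):
            continue
        if ev.kind == "icd":
            code = normalize_code(ev.value)
            for stem in spec.icd_stems:
                if code.startswith(stem):
                    counts[f"icd:{stem}"] += 1
        else:
            name = " ".join(ev.value.lower().split())
            if name in meds:
                counts[f"med:{name}"] += 1
    return counts


def _phrase_counts_for_text(
    text: str,
    phrases: list[tuple[str, ...]],
    mode: str,
    cache: dict[tuple[str, ...], np.ndarray],
) -> np.ndarray:
    """Sum of per-sentence phrase counts; cached per distinct sentence.

    Counting per sentence keeps phrase matching consistent with n-gram
    extraction (phrases never straddle a sentence boundary) and lets heavily
    repeated boilerplate be counted once.
    """
    total = np.zeros(len(phrases), dtype=np.int64)
    for sent in sentence_token_lists(text, mode):
        vec = cache.get(sent)
        if vec is None:
            vec = np.array([count_phrase(sent, p) for p in phrases], dtype=np.int64)
            cache[sent] = vec
        total += vec
    return total


def build_matrix(
    notes: list[NoteDocument],
    records: list[PatientRecord],
    spec: FeatureSpec,
    modalities=MODALITIES,
    labels: dict[str, int] | None = None,
) -> FeatureMatrix:
    """Assemble the note x feature count matrix for the requested modalities.

    Pure: identical inputs produce an identical matrix.  Row order follows
    the input note order; a note whose patient is missing from ``records``
    raises.  The full matrix equals the column-wise concatenation of the
    single-modality matrices.
    """
    unknown = set(modalities) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities {sorted(unknown)}")
    by_patient = {r.patient_id: r for r in records}
    for n in notes:
        if n.patient_id not in by_patient:
            raise KeyError(f"note {n.note_id}: patient {n.patient_id} not in records")

    columns: list[str] = []
    provenance: dict[str, dict] = {}
    phrases = spec.phrase_columns() if "notes" in modalities else []
    phrase_names = [" ".join(p) for p in phrases]
    if "notes" in modalities:
        for name, p in zip(phrase_names, phrases):
            col = f"phrase:{name}"
            columns.append(col)
            provenance[col] = {"modality": "notes", "kind": "phrase", "phrase": name}
    if "icd" in modalities:
        for s in spec.icd_stems:
            col = f"icd:{s}"
            columns.append(col)
            provenance[col] = {"modality": "icd", "kind": "icd_stem", "stem": s}
    if "med" in modalities:
        for m in spec.medications:
            col = f"med:{m}"
            columns.append(col)
            provenance[col] = {"modality": "med", "kind": "medication", "name": m}

    data = np.zeros((len(notes), len(columns)), dtype=np.int64)
    sentence_cache: dict[tuple[str, ...], np.ndarray] = {}
    n_phr = len(phrases)
    for i, note in enumerate(notes):
        off = 0
        if "notes" in modalities:
            data[i, :n_phr] = _phrase_counts_for_text(
                note.text, phrases, spec.text_normalizer, sentence_cache
            )
            off = n_phr
        if "icd" in modalities or "med" in modalities:
            ev_counts = count_events(by_patient[note.patient_id].events, note.date, spec)
            if "icd" in modalities:
                for s in spec.icd_stems:
                    data[i, off] = ev_counts[f"icd:{s}"]
                    off += 1
            if "med" in modalities:
                for m in spec.medications:
                    data[i, off] = ev_counts[f"med:{m}"]
                    off += 1

    frame = pd.DataFrame(data, index=[n.note_id for n in notes], columns=columns)
    frame.index.name = "note_id"
    lab = None
    if labels is not None:
        lab = pd.Series([labels[n.note_id] for n in notes], index=frame.index, name="label")
    return FeatureMatrix(frame=frame, provenance=provenance, labels=lab)
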