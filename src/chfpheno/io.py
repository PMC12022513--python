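"""Plain-text interchange: notes as JSONL, events and labels as CSV.

Formats
-------
notes.jsonl   one object per line: {note_id, patient_id, site, date, text}
events.csv    columns: patient_id, date, kind ("icd"|"med"), value
labels.csv    columns: note_id, label ("positive"|"negative")

Loaders normalize medication values with
:func:`chfpheno.cohort.normalize_medication` so raw prescription strings
("FUROSEMIDE 40MG PO") screen correctly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import CodedEvent, NoteDocument, PatientRecord, normalize_medication
from .synth_ehr import SyntheticCohort

__all__ = [
    "write_notes_jsonl",
    "read_notes_jsonl",
    "write_events_csv",
    "read_events_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_cohort",
    "read_records",
]


def write_notes_jsonl(notes: list[NoteDocument], path) -> None:
    with open(path, "w") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "site": n.site,
                        "date": n.date.isoformat(),
                        "text": n.text,
                    }
                )
                + "\n"
            )


def read_notes_jsonl(path) -> list[NoteDocument]:
    notes = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                notes.append(
                    NoteDocument(d["note_id"], d["patient_id"], d["site"], d["date"], d["text"])
                )
    return notes


def write_events_csv(events: list[CodedEvent], path) -> None:
    pd.DataFrame(
        [
            {"patient_id": e.patient_id, "date": e.date.isoformat(), "kind": e.kind, "value": e.value}
            for e in events
        ],
        columns=["patient_id", "date", "kind", "value"],
    ).to_csv(path, index=False)


def read_events_csv(path, normalize_meds: bool = True) -> list[CodedEvent]:
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        value = str(row["value"])
        if normalize_meds and row["kind"] == "med":
            value = normalize_medication(value)
        events.append(CodedEvent(str(row["patient_id"]), str(row["date"]), row["kind"], value))
    return events


def write_labels_csv(labels: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(labels.items()), columns=["note_id", "label"]
    ).to_csv(path, index=False)


def read_labels_csv(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["note_id"].astype(str), df["label"].astype(str)))


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Persist a generated cohort as notes.jsonl + events.csv + labels.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_notes_jsonl(cohort.notes(), out / "notes.jsonl")
    write_events_csv([e for r in cohort.records for e in r.events], out / "events.csv")
    write_labels_csv(cohort.truth_labels, out / "labels.csv")


def read_records(notes_path, events_path) -> list[PatientRecord]:
    """Assemble PatientRecords from the interchange files."""
    notes = read_notes_jsonl(notes_path)
    events = read_events_csv(events_path)
    by_pid: dict[str, PatientRecord] = {}
    for n in notes:
        by_pid.setdefault(n.patient_id, PatientRecord(n.patient_id)).notes.append(n)
    for e in events:
        by_pid.setdefault(e.patient_id, PatientRecord(e.patient_id)).events.append(e)
    return [by_pid[k] for k in sorted(by_pid)]
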