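"""Synthetic EHR cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-hospital population screened into four groups by
CHF diagnosis codes and medications.  Each patient carries one clinical note
assembled from sentence templates (header, findings, plan, boilerplate) plus
filler sentences to reach a target length, and a dated stream of ICD and
medication events placed around the note date.  Positive notes always contain
at least one CHF affirmation phrase; negative notes may contain the
confounders seen in real charts — explicit negations ("no CHF"), family
history ("CHF mother"), templated boilerplate ("tell your doctor if you have
CHF"), and bare screening keywords ("heart") — none of which make a note
positive.  A note stating a personal history of CHF is positive.

Default rates are population-like: group mix ≈ (14.0%, 4.1%, 34.2%, 47.7%)
and within-group positive prevalence ≈ (10%, 9.8%, 0.88%, 0.21%), so an
unselected cohort is ~2% positive; enrichment for modelling is the job of
:func:`chfpheno.cohort.sample_notes`.  Note lengths are log-uniform over
1,907–60,870 characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta

import numpy as np

from .cohort import (
    DEFAULT_MEDICATIONS,
    CodedEvent,
    NoteDocument,
    PatientRecord,
    ScreeningGroup,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "inject_confounder",
    "CONFOUNDER_KINDS",
    "AFFIRMATION_PHRASES",
]

#: Phrases whose presence affirms the phenotype (personal diagnosis).
AFFIRMATION_PHRASES: tuple[str, ...] = (
    "chf",
    "congestive heart failure",
    "history of chf",
)

_AFFIRMATION_SENTENCES = (
    "The patient has a known diagnosis of congestive heart failure",
    "Assessment and plan: CHF exacerbation, continue aggressive diuresis",
    "Patient with CHF on home furosemide and lisinopril",
    "Impression: acute on chronic congestive heart failure",
    "Dx CHF confirmed on prior echocardiogram",
    "She was admitted with congestive heart failure and volume overload",
    "Exam notable for ascites and elevated JVP consistent with CHF",
    "Known CHF with reduced ejection fraction followed by cardiology",
)

_RESOLVED_SENTENCES = (
    "History of CHF, currently well compensated and asymptomatic",
    "Remote history of CHF with no current symptoms on exam today",
    "History of congestive heart failure, stable on current regimen",
)

_NEGATION_SENTENCES = (
    "No CHF",
    "Unlikely CHF given the normal echocardiogram",
    "I do not feel like this is consistent with congestive heart failure",
    "No evidence of congestive heart failure on today's exam",
)

_FAMILY_SENTENCES = (
    "Family history: CHF mother, diabetes father",
    "CHF father, deceased at age 80",
    "Family history notable for CHF mother and hypertension",
)

_TEMPLATE_SENTENCES = (
    "Tell your doctor if you have CHF, kidney disease, or liver problems",
    "Medication insert: tell your doctor if you have CHF before starting this drug",
    "Discharge instructions: tell your doctor if you have CHF or trouble breathing",
)

# questionnaire checkbox lines; injected alongside template boilerplate
_CHECKLIST_SENTENCES = (
    "Past medical history checklist: [ ] CHF [ ] asthma [ ] stroke",
    "Intake form: ( ) congestive heart failure ( ) copd ( ) cancer",
)

CONFOUNDER_KINDS = ("negation", "family-history", "template", "resolved-history")

_CONFOUNDER_POOLS = {
    "negation": _NEGATION_SENTENCES,
    "family-history": _FAMILY_SENTENCES,
    "template": _TEMPLATE_SENTENCES,
    "resolved-history": _RESOLVED_SENTENCES,
}

# Benign filler; several sentences carry the bare screening keyword "heart"
# so keyword-filtered sampling is exercisable on negative notes.
_KEYWORD_FILLER = (
    "Heart rate 72 and regular",
    "Heart sounds normal with no murmurs rubs or gallops",
    "Regular heart rhythm on auscultation",
)

_FILLER_SENTENCES = (
    "Vital signs reviewed and stable",
    "Blood pressure 128 over 76 in the right arm",
    "Lungs clear to auscultation bilaterally",
    "Abdomen soft and nontender without distension",
    "No lower extremity edema appreciated",
    "Respiratory rate 16 with oxygen saturation 98 percent on room air",
    "Patient denies fever chills or night sweats",
    "Review of systems otherwise negative",
    "Medication list reviewed and reconciled with the patient",
    "Continue current medications as prescribed",
    "Follow up in clinic in three months",
    "Labs reviewed including basic metabolic panel",
    "Creatinine stable at baseline",
    "Electrolytes within normal limits",
    "Patient ambulating independently without assistance",
    "Diet and exercise counseling provided",
    "Tobacco cessation discussed patient agreeable",
    "Sleep quality reported as fair",
    "Appetite normal with stable weight",
    "Skin warm dry and intact",
    "Neurologic exam grossly nonfocal",
    "Alert and oriented to person place and time",
    "No acute distress noted during the visit",
    "Plan discussed with the patient who verbalized understanding",
    "Return precautions reviewed in detail",
    "Influenza vaccination offered and administered",
    "Screening colonoscopy up to date",
    "Annual laboratory work ordered today",
    "Physical therapy referral placed for deconditioning",
    "Pain well controlled with acetaminophen as needed",
    "Blood glucose log reviewed with the patient",
    "Renal function will be monitored at the next visit",
    "Patient tolerated the examination well",
    "Extremities without clubbing or cyanosis",
    "Mild osteoarthritis of the knees unchanged",
    "Seasonal allergies managed with loratadine",
    "Hearing and vision screening unremarkable",
    "Gait steady without assistive device",
)

_HEADER_SENTENCES = (
    "Progress note documented during today's clinic visit",
    "Outpatient follow up visit note",
    "Hospital progress note for ongoing care",
    "Clinic note for routine evaluation",
)

_CHF_ICD_CODES = ("I50.9", "I50.32", "I50.22", "I50.43", "428.0", "428.32", "4280")
_BENIGN_ICD_CODES = ("E11.9", "J45.909", "Z00.00", "M54.5", "I10")
_CHF_MED_POOL = ("furosemide", "lisinopril", "omeprazole", "amlodipine", "enalapril")
_BENIGN_MEDS = ("metformin", "atorvastatin", "albuterol", "sertraline")

_GROUP_ORDER = tuple(ScreeningGroup)
_NOTE_DATE_LO = _date(2010, 1, 1).toordinal()
_NOTE_DATE_HI = _date(2023, 12, 31).toordinal()
_KEYWORD_SENTENCE_RATE = 0.9  # chance a note carries a bare "heart" sentence


def _default_group_weights() -> dict[ScreeningGroup, float]:
    return {
        ScreeningGroup.ICD_POS_MED_POS: 0.140,
        ScreeningGroup.ICD_POS_MED_NEG: 0.041,
        ScreeningGroup.ICD_NEG_MED_POS: 0.342,
        ScreeningGroup.ICD_NEG_MED_NEG: 0.477,
    }


def _default_prevalences() -> dict[ScreeningGroup, float]:
    return {
        ScreeningGroup.ICD_POS_MED_POS: 0.100,
        ScreeningGroup.ICD_POS_MED_NEG: 0.098,
        ScreeningGroup.ICD_NEG_MED_POS: 0.0088,
        ScreeningGroup.ICD_NEG_MED_NEG: 0.0021,
    }


def _default_confounder_rates() -> dict[str, float]:
    return {
        "family-history": 0.10,
        "template": 0.15,
        "negation": 0.10,
        "resolved-history": 0.10,
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 1000
    site_labels: tuple[str, ...] = ("MGH", "BIDMC")
    group_weights: dict[ScreeningGroup, float] = field(default_factory=_default_group_weights)
    positive_prevalence_per_group: dict[ScreeningGroup, float] = field(
        default_factory=_default_prevalences
    )
    confounder_rates: dict[str, float] = field(default_factory=_default_confounder_rates)
    note_length_range: tuple[int, int] = (1907, 60870)
    event_window_days: int = 540
    #: fraction of events deliberately placed beyond +/-18 calendar months,
    #: to exercise the feature-window boundary
    outside_window_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.site_labels:
            raise ValueError("site_labels must be non-empty")
        total = sum(self.group_weights.get(g, 0.0) for g in _GROUP_ORDER)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_weights must sum to 1 (got {total})")
        for g in _GROUP_ORDER:
            p = self.positive_prevalence_per_group.get(g, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"positive_prevalence_per_group[{g.value}] not in [0,1]")
        for kind, rate in self.confounder_rates.items():
            if kind not in CONFOUNDER_KINDS:
                raise ValueError(f"confounder_rates has unknown kind {kind!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"confounder_rates[{kind}] not in [0,1]")
        lo, hi = self.note_length_range
        if lo < 1 or lo > hi:
            raise ValueError("note_length_range must satisfy 1 <= min <= max")
        if self.event_window_days < 1:
            raise ValueError("event_window_days must be >= 1")
        if not 0.0 <= self.outside_window_fraction <= 1.0:
            raise ValueError("outside_window_fraction not in [0,1]")


@dataclass
class SyntheticCohort:
    """Generated records plus ground truth and generation provenance."""

    records: list[PatientRecord]
    truth_labels: dict[str, str]  # note_id -> "positive" | "negative"
    group_assignments: dict[str, ScreeningGroup]  # patient_id -> group
    provenance: dict[str, list[str]]  # note_id -> injected phenomena
    config: GeneratorConfig

    def notes(self) -> list[NoteDocument]:
        return [n for r in self.records for n in r.notes]

    def labels01(self) -> dict[str, int]:
        return {k: int(v == "positive") for k, v in self.truth_labels.items()}


def inject_confounder(note_text: str, kind: str, rng: np.random.Generator) -> str:
    """Append one confounder sentence of the requested kind.

    The phenotype label is unchanged by construction: every pool sentence is
    label-neutral for the note it is added to.  On an empty note the returned
    text is the confounder sentence alone.
    """
    if kind not in _CONFOUNDER_POOLS:
        raise ValueError(f"unknown confounder kind {kind!r}; expected one of {CONFOUNDER_KINDS}")
    pool = _CONFOUNDER_POOLS[kind]
    sentence = pool[int(rng.integers(len(pool)))] + "."
    if not note_text:
        return sentence
    return note_text.rstrip() + " " + sentence


def _pick(rng: np.random.Generator, pool: tuple[str, ...]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _assemble_note_text(
    rng: np.random.Generator,
    header: str,
    content: list[str],
    length_range: tuple[int, int],
    with_keyword_sentence: bool,
) -> str:
    lo, hi = length_range
    target = float(np.exp(rng.uniform(np.log(lo), np.log(max(lo + 1, hi - 150)))))
    sentences = [header]
    if with_keyword_sentence:
        sentences.append(_pick(rng, _KEYWORD_FILLER))
    sentences.extend(content)
    text = ". ".join(sentences) + "."
    while len(text) < max(target, lo):
        nxt = _pick(rng, _FILLER_SENTENCES)
        if len(text) + len(nxt) + 2 > hi:
            break
        text = text + " " + nxt + "."
    # pad with the shortest filler if still under the minimum (tiny ranges)
    while len(text) < lo and len(text) + 30 <= hi:
        text = text + " Vital signs reviewed and stable."
    return text


def _random_note_date(rng: np.random.Generator) -> _date:
    return _date.fromordinal(int(rng.integers(_NOTE_DATE_LO, _NOTE_DATE_HI + 1)))


def _event_offset_days(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    if rng.random() < cfg.outside_window_fraction:
        # safely beyond 18 calendar months in either direction
        mag = int(rng.integers(560, 721))
    else:
        mag = int(rng.integers(0, cfg.event_window_days + 1))
    sign = -1 if rng.random() < 0.5 else 1
    return sign * mag


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a cohort; deterministic for a fixed config seed.

    Guarantees, by construction:

    * ICD+ patients have >= 1 event with code stem 428/I50 and ICD- patients
      have none; likewise MED+/- for the screening medications, so re-running
      :func:`chfpheno.cohort.assign_group` reproduces ``group_assignments``.
    * every positive note contains >= 1 affirmation phrase; negative notes
      mention CHF only inside confounder contexts (negations, family history,
      boilerplate) or as bare keywords, so labels are re-derivable from
      ``provenance``.
    * all note lengths fall inside ``note_length_range``.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()

    root = np.random.SeedSequence(cfg.seed)
    patient_seeds = root.spawn(cfg.n_patients)
    weights = np.array([cfg.group_weights.get(g, 0.0) for g in _GROUP_ORDER], dtype=float)
    weights = weights / weights.sum()

    records: list[PatientRecord] = []
    truth: dict[str, str] = {}
    groups: dict[str, ScreeningGroup] = {}
    provenance: dict[str, list[str]] = {}
    rates = {k: cfg.confounder_rates.get(k, 0.0) for k in CONFOUNDER_KINDS}

    for i, seed_i in enumerate(patient_seeds):
        rng = np.random.default_rng(seed_i)
        pid = f"p{i:06d}"
        site = cfg.site_labels[int(rng.integers(len(cfg.site_labels)))]
        group = _GROUP_ORDER[int(rng.choice(len(_GROUP_ORDER), p=weights))]
        groups[pid] = group
        note_date = _random_note_date(rng)
        note_id = f"{pid}-n0"

        positive = rng.random() < cfg.positive_prevalence_per_group.get(group, 0.0)
        prov: list[str] = []
        content: list[str] = []
        if positive:
            n_aff = 1 + int(rng.poisson(1.5))
            content.extend(_pick(rng, _AFFIRMATION_SENTENCES) for _ in range(n_aff))
            prov.append("affirmation")
            if rng.random() < rates["resolved-history"]:
                content.append(_pick(rng, _RESOLVED_SENTENCES))
                prov.append("resolved-history")
        else:
            if rng.random() < rates["negation"]:
                content.append(_pick(rng, _NEGATION_SENTENCES))
                prov.append("negation")
        if rng.random() < rates["family-history"]:
            content.append(_pick(rng, _FAMILY_SENTENCES))
            prov.append("family-history")
        if rng.random() < rates["template"]:
            content.append(_pick(rng, _TEMPLATE_SENTENCES))
            if rng.random() < 0.5:
                content.append(_pick(rng, _CHECKLIST_SENTENCES))
            prov.append("template")

        order = rng.permutation(len(content))
        content = [content[j] for j in order]
        # header drawn from a small fixed pool: keeps the n-gram vocabulary
        # bounded so discovery on large cohorts stays cheap
        header = _pick(rng, _HEADER_SENTENCES)
        text = _assemble_note_text(
            rng, header, content, cfg.note_length_range,
            with_keyword_sentence=rng.random() < _KEYWORD_SENTENCE_RATE,
        )

        events: list[CodedEvent] = []
        icd_pos = group in (ScreeningGroup.ICD_POS_MED_POS, ScreeningGroup.ICD_POS_MED_NEG)
        med_pos = group in (ScreeningGroup.ICD_POS_MED_POS, ScreeningGroup.ICD_NEG_MED_POS)
        if icd_pos:
            n_icd = 1 + int(rng.poisson(1.5)) + (int(rng.poisson(1.0)) if positive else 0)
            for _ in range(n_icd):
                d = note_date + timedelta(days=_event_offset_days(rng, cfg))
                events.append(CodedEvent(pid, d, "icd", _pick(rng, _CHF_ICD_CODES)))
        if med_pos:
            n_med = 1 + int(rng.poisson(1.5)) + (int(rng.poisson(1.0)) if positive else 0)
            for _ in range(n_med):
                d = note_date + timedelta(days=_event_offset_days(rng, cfg))
                events.append(CodedEvent(pid, d, "med", _pick(rng, _CHF_MED_POOL)))
        for _ in range(int(rng.poisson(1.0))):
            d = note_date + timedelta(days=_event_offset_days(rng, cfg))
            events.append(CodedEvent(pid, d, "icd", _pick(rng, _BENIGN_ICD_CODES)))
        for _ in range(int(rng.poisson(1.0))):
            d = note_date + timedelta(days=_event_offset_days(rng, cfg))
            events.append(CodedEvent(pid, d, "med", _pick(rng, _BENIGN_MEDS)))

        note = NoteDocument(note_id, pid, site, note_date, text)
        records.append(PatientRecord(pid, notes=[note], events=events))
        truth[note_id] = "positive" if positive else "negative"
        provenance[note_id] = prov

    return SyntheticCohort(records, truth, groups, provenance, cfg)
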