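"""External validation, bootstrap intervals, and population error extrapolation.

The modelling sample is deliberately enriched for likely-positive screening
groups, so its error rate does not transfer to an unselected hospital
population.  The extrapolation combines, per screening group g, the
misclassification rate measured in the annotated sample (Pe_g) with the
positive prevalence of the group observed in a random sample (p_g):

    P(E) = sum_g Pe_g * p_g

computed from raw counts, never from pre-rounded rates.  Note the weights
p_g are within-group positive prevalences and do not sum to one; the
estimate is reported with that caveat attached (see
``PopulationEstimate.prevalence_weight_total``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    NoteDocument,
    PatientRecord,
    ScreeningCriteria,
    ScreeningGroup,
    assign_group,
)
from .models import auroc as _auroc
from sklearn.metrics import average_precision_score

__all__ = [
    "GroupStats",
    "GroupErrorTable",
    "PopulationEstimate",
    "CIConfig",
    "estimate_population_error",
    "bootstrap_ci",
    "cross_site_eval",
    "classify_random_sample",
]


@dataclass
class GroupStats:
    """Raw counts for one screening group."""

    error_count: int = 0
    n_annotated: int = 0
    positive_count: int = 0
    n_random: int = 0

    def validate(self, group: str) -> None:
        if self.error_count > self.n_annotated:
            raise ValueError(f"{group}: error_count exceeds n_annotated")
        if self.positive_count > self.n_random:
            raise ValueError(f"{group}: positive_count exceeds n_random")
        if min(self.error_count, self.n_annotated, self.positive_count, self.n_random) < 0:
            raise ValueError(f"{group}: counts must be nonnegative")


@dataclass
class GroupErrorTable:
    """Per-group annotated-sample error counts and random-sample prevalence."""

    groups: dict[ScreeningGroup, GroupStats] = field(default_factory=dict)

    def validate(self) -> None:
        for g, st in self.groups.items():
            st.validate(g.value)

    def error_rate(self, g: ScreeningGroup) -> float:
        st = self.groups[g]
        if st.n_annotated == 0:
            raise ValueError(f"{g.value}: zero annotated denominator")
        return st.error_count / st.n_annotated

    def prevalence(self, g: ScreeningGroup) -> float:
        st = self.groups[g]
        if st.n_random == 0:
            raise ValueError(f"{g.value}: zero random-sample denominator")
        return st.positive_count / st.n_random

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, st in self.groups.items():
            rows.append(
                {
                    "group": g.value,
                    "error_count": st.error_count,
                    "n_annotated": st.n_annotated,
                    "error_rate_pct": 100.0 * st.error_count / st.n_annotated
                    if st.n_annotated
                    else float("nan"),
                    "positive_count": st.positive_count,
                    "n_random": st.n_random,
                    "prevalence_pct": 100.0 * st.positive_count / st.n_random
                    if st.n_random
                    else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroupErrorTable":
        groups = {}
        for _, row in df.iterrows():
            groups[ScreeningGroup(row["group"])] = GroupStats(
                error_count=int(row["error_count"]),
                n_annotated=int(row["n_annotated"]),
                positive_count=int(row["positive_count"]),
                n_random=int(row["n_random"]),
            )
        return cls(groups=groups)

    @classmethod
    def from_csv(cls, path) -> "GroupErrorTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class PopulationEstimate:
    value: float
    per_group_contributions: dict[ScreeningGroup, float]
    #: sum of the p_g weights — deliberately not 1; the formula weights by
    #: within-group positive prevalence, not by group share of the population
    prevalence_weight_total: float

    def report(self) -> str:
        lines = [f"estimated population error rate: {self.value:.4f} ({100*self.value:.1f}%)"]
        for g, c in self.per_group_contributions.items():
            lines.append(f"  {g.value}: contribution {c:.6f}")
        lines.append(
            "note: prevalence weights sum to "
            f"{self.prevalence_weight_total:.4f} (within-group prevalences, not a partition)"
        )
        return "\n".join(lines)


def estimate_population_error(
    table: GroupErrorTable, weighting: str = "prevalence"
) -> PopulationEstimate:
    """P(E) = sum over groups of error_rate x weight.

    With the default ``weighting='prevalence'`` the weight is the group's
    positive prevalence in the random sample — the published form, whose
    weights do not sum to one.  ``weighting='group_share'`` instead weighs
    each group's error rate by its share of the random sample (weights sum
    to one), answering "what fraction of a random sample would be
    misclassified"; it is offered as an alternative reading, not as the
    original method.  Both factors come from raw counts.  A group with a
    zero denominator raises; groups absent from the table are not summed.
    """
    if weighting not in ("prevalence", "group_share"):
        raise ValueError(f"unknown weighting {weighting!r}")
    table.validate()
    contributions: dict[ScreeningGroup, float] = {}
    weight_total = 0.0
    n_random_total = sum(st.n_random for st in table.groups.values())
    for g, st in table.groups.items():
        pe = table.error_rate(g)
        if weighting == "prevalence":
            w = table.prevalence(g)
        else:
            if n_random_total == 0:
                raise ValueError("group_share weighting needs a random sample")
            w = st.n_random / n_random_total
        contributions[g] = pe * w
        weight_total += w
    return PopulationEstimate(
        value=float(sum(contributions.values())),
        per_group_contributions=contributions,
        prevalence_weight_total=weight_total,
    )


@dataclass
class CIConfig:
    n_boot: int = 10_000
    level: float = 0.95
    seed: int = 0
    #: resampling unit: "note" (iid rows) or "patient" (cluster bootstrap)
    unit: str = "note"

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0,1)")
        if self.unit not in ("note", "patient"):
            raise ValueError("unit must be 'note' or 'patient'")


def _metric_fn(metric: str):
    if metric == "auroc":
        return _auroc
    if metric == "auprc":
        return lambda s, y: float(average_precision_score(np.asarray(y).astype(int), s))
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_ci(
    scores,
    labels,
    metric: str = "auroc",
    config: CIConfig | None = None,
    patient_ids=None,
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for AUROC or AUPRC.

    Resamples (score, label) pairs with replacement; a resample containing a
    single class is redrawn.  With ``unit='patient'`` whole patients are
    resampled (notes from one patient are correlated).  Deterministic given
    the config seed.
    """
    cfg = config or CIConfig()
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fn = _metric_fn(metric)
    point = fn(s, y)
    rng = np.random.default_rng(cfg.seed)

    if cfg.unit == "patient":
        if patient_ids is None:
            raise ValueError("patient-unit bootstrap requires patient_ids")
        pids = np.asarray(patient_ids)
        unique = np.unique(pids)
        members = {p: np.flatnonzero(pids == p) for p in unique}

    stats = np.empty(cfg.n_boot)
    n = len(y)
    for b in range(cfg.n_boot):
        for _attempt in range(1000):
            if cfg.unit == "note":
                idx = rng.integers(0, n, n)
            else:
                chosen = rng.choice(unique, size=len(unique), replace=True)
                idx = np.concatenate([members[p] for p in chosen])
            yb = y[idx]
            if yb.min() != yb.max():
                break
        else:
            raise RuntimeError("could not draw a two-class resample")
        stats[b] = fn(s[idx], yb)
    alpha = 1.0 - cfg.level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(point), float(lo), float(hi)


def cross_site_eval(
    train_notes: list[NoteDocument],
    train_records: list[PatientRecord],
    train_labels: dict[str, int],
    test_notes: list[NoteDocument],
    test_records: list[PatientRecord],
    test_labels: dict[str, int],
    config=None,
    seed: int = 0,
    ci_config: CIConfig | None = None,
) -> dict:
    """Train the full pipeline on one site and score the held-out site.

    The lexicon is discovered and the model fitted on the training site
    only; the training-site vocabulary is closed, so phrases unique to the
    test site contribute no columns.  Overlapping patient ids across sites
    raise (leakage guard).
    """
    from .pipeline import PipelineConfig, fit_pipeline

    overlap = {r.patient_id for r in train_records} & {r.patient_id for r in test_records}
    if overlap:
        raise ValueError(f"patient overlap across sites: {sorted(overlap)[:5]} ...")
    y_test = np.array([test_labels[n.note_id] for n in test_notes])
    if y_test.min() == y_test.max():
        raise ValueError("test site contains a single class")

    cfg = config or PipelineConfig()
    fitted = fit_pipeline(train_notes, train_records, train_labels, cfg, seed=seed)
    p = fitted.predict_proba(test_notes, test_records)
    ci_cfg = ci_config or CIConfig(seed=seed)
    out = {}
    for metric in ("auroc", "auprc"):
        point, lo, hi = bootstrap_ci(p, y_test, metric=metric, config=ci_cfg)
        out[metric] = point
        out[f"{metric}_ci"] = (lo, hi)
    out["n_test"] = len(y_test)
    out["scores"] = p
    out["labels"] = y_test
    return out


def classify_random_sample(
    notes: list[NoteDocument],
    records: list[PatientRecord],
    fitted_pipeline,
    criteria: ScreeningCriteria | None = None,
) -> GroupErrorTable:
    """Fill the prevalence side of a GroupErrorTable from an unselected sample.

    Each patient contributes one note; model-positive calls (at the fitted
    Youden cutoff) are tallied per screening group.
    """
    if getattr(fitted_pipeline, "threshold", None) is None:
        raise ValueError("pipeline must be fitted with a decision threshold")
    criteria = criteria or ScreeningCriteria()
    by_patient = {r.patient_id: r for r in records}
    calls = fitted_pipeline.classify(notes, records)
    table = GroupErrorTable(groups={g: GroupStats() for g in ScreeningGroup})
    for note, call in zip(notes, calls):
        g = assign_group(by_patient[note.patient_id], criteria)
        st = table.groups[g]
        st.n_random += 1
        st.positive_count += int(call)
    return table
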