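"""End-to-end pipeline plumbing: lexicon -> features -> classifier.

Used by the Model/Results facade, the cross-site evaluator, and the CLI.
Keyword discovery uses only the ICD screening status of each note's patient
as a proxy label, so lexicon construction never sees manual annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    DEFAULT_ICD_STEMS,
    DEFAULT_MEDICATIONS,
    NoteDocument,
    PatientRecord,
    ScreeningCriteria,
    ScreeningGroup,
    assign_group,
)
from .features import MODALITIES, FeatureMatrix, FeatureSpec, build_matrix
from .keywords import (
    DEFAULT_CURATED_KEYWORDS,
    DEFAULT_NEGATION_TEMPLATES,
    KeywordLexicon,
    discover_keywords,
)
from .models import (
    HyperparamSpace,
    make_estimator,
    median_hyperparams,
    nested_cv,
    youden_cutoff,
)

__all__ = ["PipelineConfig", "FittedPipeline", "fit_pipeline", "proxy_icd_labels", "build_features"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a lexicon + feature + model fit."""

    curated: tuple[str, ...] = DEFAULT_CURATED_KEYWORDS
    discover: bool = True
    alpha: float = 0.05
    correction: str = "bh"
    min_notes: int = 5
    max_n: int = 3
    negation_templates: tuple[str, ...] = DEFAULT_NEGATION_TEMPLATES
    modalities: tuple[str, ...] = MODALITIES
    icd_stems: tuple[str, ...] = DEFAULT_ICD_STEMS
    medications: tuple[str, ...] = DEFAULT_MEDICATIONS
    event_window_months: int = 18
    text_normalizer: str = "both"
    space: HyperparamSpace = field(default_factory=HyperparamSpace)
    k_inner: int = 5
    #: optional deployment pruning: zero LR coefficients with |coef| below
    #: this after the final refit; None disables (default)
    coef_prune_threshold: float | None = None


def proxy_icd_labels(
    notes: list[NoteDocument],
    records: list[PatientRecord],
    criteria: ScreeningCriteria | None = None,
) -> np.ndarray:
    """ICD screening status of each note's patient (keyword-discovery proxy)."""
    criteria = criteria or ScreeningCriteria()
    status = {
        r.patient_id: assign_group(r, criteria)
        in (ScreeningGroup.ICD_POS_MED_POS, ScreeningGroup.ICD_POS_MED_NEG)
        for r in records
    }
    return np.array([status[n.patient_id] for n in notes])


def build_lexicon(
    notes: list[NoteDocument],
    records: list[PatientRecord],
    cfg: PipelineConfig,
) -> KeywordLexicon:
    if not cfg.discover:
        from .keywords import select_keywords, augment_negations

        lex = select_keywords([], alpha=cfg.alpha, correction=cfg.correction,
                              curated=cfg.curated, mode=cfg.text_normalizer)
        if cfg.negation_templates:
            lex = augment_negations(lex, cfg.negation_templates, cfg.text_normalizer)
        return lex
    proxy = proxy_icd_labels(notes, records)
    return discover_keywords(
        notes,
        proxy,
        max_n=cfg.max_n,
        min_notes=cfg.min_notes,
        alpha=cfg.alpha,
        correction=cfg.correction,
        curated=cfg.curated,
        negation_templates=cfg.negation_templates,
        mode=cfg.text_normalizer,
    )


def build_features(
    notes: list[NoteDocument],
    records: list[PatientRecord],
    lexicon: KeywordLexicon,
    cfg: PipelineConfig,
    labels: dict[str, int] | None = None,
) -> FeatureMatrix:
    spec = FeatureSpec(
        lexicon=lexicon,
        icd_stems=cfg.icd_stems,
        medications=cfg.medications,
        event_window_months=cfg.event_window_months,
        text_normalizer=cfg.text_normalizer,
    )
    return build_matrix(notes, records, spec, modalities=cfg.modalities, labels=labels)


@dataclass
class FittedPipeline:
    lexicon: KeywordLexicon
    config: PipelineConfig
    estimator: object
    feature_columns: list[str]
    threshold: float | None
    chosen_hyperparams: dict

    def _featurize(self, notes, records) -> np.ndarray:
        fm = build_features(notes, records, self.lexicon, self.config)
        return fm.frame[self.feature_columns].to_numpy(dtype=float)

    def predict_proba(self, notes, records) -> np.ndarray:
        return self.estimator.predict_proba(self._featurize(notes, records))[:, 1]

    def classify(self, notes, records) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("pipeline has no decision threshold")
        return (self.predict_proba(notes, records) >= self.threshold).astype(int)


def fit_pipeline(
    notes: list[NoteDocument],
    records: list[PatientRecord],
    labels: dict[str, int],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> FittedPipeline:
    """Discover the lexicon, run nested CV, refit on all training data.

    The deployed estimator uses the median hyperparameters across the outer
    folds; its decision threshold is the mean of the per-fold Youden cutoffs.
    """
    cfg = cfg or PipelineConfig()
    lexicon = build_lexicon(notes, records, cfg)
    fm = build_features(notes, records, lexicon, cfg, labels=labels)
    y = fm.labels.to_numpy()
    groups = np.array([n.patient_id for n in notes])
    report = nested_cv(fm.frame, y, cfg.space, k_outer=5, k_inner=cfg.k_inner,
                       seed=seed, groups=groups)
    params = median_hyperparams(report)
    est = make_estimator(cfg.space.model_kind, params, seed=seed)
    est.fit(fm.frame.to_numpy(dtype=float), y)
    if cfg.coef_prune_threshold is not None and cfg.space.model_kind == "elastic_net_lr":
        lr = est.named_steps["lr"]
        lr.coef_[np.abs(lr.coef_) < cfg.coef_prune_threshold] = 0.0
    threshold = float(np.mean([f.youden.threshold for f in report.fold_results
                               if np.isfinite(f.youden.threshold)]))
    fitted = FittedPipeline(
        lexicon=lexicon,
        config=cfg,
        estimator=est,
        feature_columns=list(fm.frame.columns),
        threshold=threshold,
        chosen_hyperparams=params,
    )
    fitted.cv_report = report
    return fitted
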