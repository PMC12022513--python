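"""Model/Results facade over the phenotyping pipeline.

Mirrors the fit-then-results idiom of statistical modelling packages: a
:class:`CHFPhenotyper` is constructed from data (a feature matrix, or a raw
cohort via :meth:`CHFPhenotyper.from_cohort`), ``fit()`` runs nested
cross-validation and a final refit, and the returned
:class:`CHFPhenotyperResults` carries fold metrics, cutoffs, importances, a
``summary()`` table, and plotting helpers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .models import (
    CVReport,
    HyperparamSpace,
    ImportanceReport,
    feature_importance,
    make_estimator,
    median_hyperparams,
    nested_cv,
)
from .pipeline import PipelineConfig, build_features, build_lexicon

__all__ = ["CHFPhenotyper", "CHFPhenotyperResults"]


class CHFPhenotyper:
    """CHF note-phenotyping classifier with nested-CV evaluation.

    Parameters
    ----------
    matrix : FeatureMatrix
        Per-note counts with labels attached.
    patient_ids : array-like, optional
        Grouping key for patient-grouped folds (recommended whenever one
        patient contributes several notes).
    space : HyperparamSpace, optional
        Search ranges and budget; defaults to the elastic-net LR space.
    """

    def __init__(self, matrix: FeatureMatrix, patient_ids=None, space=None):
        if matrix.labels is None:
            raise ValueError("matrix must carry labels")
        self.matrix = matrix
        self.patient_ids = None if patient_ids is None else np.asarray(patient_ids)
        self.space = space or HyperparamSpace()

    @classmethod
    def from_cohort(cls, notes, records, labels, config: PipelineConfig | None = None,
                    space=None):
        """Build lexicon + features from raw notes/records, then the model."""
        cfg = config or PipelineConfig()
        lexicon = build_lexicon(notes, records, cfg)
        fm = build_features(notes, records, lexicon, cfg, labels=labels)
        model = cls(fm, patient_ids=[n.patient_id for n in notes],
                    space=space or cfg.space)
        model.lexicon = lexicon
        model.config = cfg
        return model

    def fit(self, k_outer: int = 5, k_inner: int = 5, seed: int = 0) -> "CHFPhenotyperResults":
        y = self.matrix.labels.to_numpy()
        report = nested_cv(
            self.matrix.frame, y, self.space,
            k_outer=k_outer, k_inner=k_inner, seed=seed, groups=self.patient_ids,
        )
        params = median_hyperparams(report)
        final = make_estimator(self.space.model_kind, params, seed=seed)
        final.fit(self.matrix.frame.to_numpy(dtype=float), y)
        return CHFPhenotyperResults(self, report, final, params)


class CHFPhenotyperResults:
    """Fitted-pipeline results: fold metrics, final refit, importances."""

    def __init__(self, model: CHFPhenotyper, cv_report: CVReport, final_estimator, params):
        self.model = model
        self.cv_report = cv_report
        self.final_estimator = final_estimator
        self.final_hyperparams = params

    # -- headline numbers ---------------------------------------------------
    @property
    def mean_auroc(self) -> float:
        return self.cv_report.mean_auroc

    @property
    def mean_auprc(self) -> float:
        return self.cv_report.mean_auprc

    @property
    def youden_cutoffs(self) -> list[float]:
        return [f.youden.threshold for f in self.cv_report.fold_results]

    def importance(self, kind: str | None = None) -> ImportanceReport:
        if kind is None:
            kind = "lr_coefficient" if self.cv_report.model_kind == "elastic_net_lr" else "rf_gini"
        return feature_importance(
            self.final_estimator, kind, list(self.model.matrix.frame.columns)
        )

    def predict_proba(self, X=None) -> np.ndarray:
        Xa = self.model.matrix.frame.to_numpy(dtype=float) if X is None else np.asarray(X, float)
        return self.final_estimator.predict_proba(Xa)[:, 1]

    def summary(self) -> str:
        rep = self.cv_report
        lines = [
            "CHF phenotyping model — nested cross-validation",
            "=" * 52,
            f"model: {rep.model_kind}   folds: {len(rep.fold_results)}   seed: {rep.seed}",
            f"features: {self.model.matrix.frame.shape[1]}   notes: {self.model.matrix.frame.shape[0]}",
            "",
            rep.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            f"mean outer AUROC: {rep.mean_auroc:.3f}",
            f"mean outer AUPRC: {rep.mean_auprc:.3f}",
            f"final refit hyperparameters (median across folds): {self.final_hyperparams}",
        ]
        top = self.importance().ranked[:10]
        lines.append("top features by |importance|:")
        for name, val in top:
            lines.append(f"  {name:<45s} {val:+.3f}")
        return "\n".join(lines)

    # -- plots --------------------------------------------------------------
    def plot_roc(self, ax=None):
        """Pooled outer-fold ROC curve."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr, _ = roc_curve(self.cv_report.pooled_labels, self.cv_report.pooled_scores)
        ax.plot(fpr, tpr, label=f"AUROC (fold mean) = {self.mean_auroc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def plot_pr(self, ax=None):
        """Pooled outer-fold precision-recall curve."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import precision_recall_curve

        if ax is None:
            _, ax = plt.subplots()
        prec, rec, _ = precision_recall_curve(
            self.cv_report.pooled_labels, self.cv_report.pooled_scores
        )
        ax.step(rec, prec, where="post", label=f"AUPRC (fold mean) = {self.mean_auprc:.3f}")
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.legend()
        return ax
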