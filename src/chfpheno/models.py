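"""Nested cross-validated classifiers with hyperparameter search.

Two model families are supported: an elastic-net-penalized logistic
regression (saga solver behind a standardizing pipeline) and a random
forest.  Hyperparameters are chosen per outer fold by maximizing the mean
inner-fold AUROC over a budgeted stream of sampled candidates; the candidate
stream is a seeded prefix sequence, so enlarging the budget can only extend
the set of candidates considered (best inner AUROC is monotone in budget).
A per-fold Youden-index cutoff converts probabilities to binary calls.

Fold splitting is grouped by patient by default — all notes of a patient
stay in one fold — and stratified by label, because repeated notes from one
patient are near-duplicates that would otherwise leak across folds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.metrics import average_precision_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "HyperparamSpace",
    "FoldResult",
    "CVReport",
    "CutoffResult",
    "ImportanceReport",
    "auroc",
    "evaluate",
    "youden_cutoff",
    "nested_cv",
    "feature_importance",
    "median_hyperparams",
    "make_estimator",
]


@dataclass
class HyperparamSpace:
    """Search ranges for one model family plus the evaluation budget.

    Logistic regression: penalty strength C log-uniform on
    [c_low, c_high] and l1_ratio uniform on [0, 1].  Random forest:
    min_samples_leaf, n_estimators, max_depth (integer-uniform) and
    ccp_alpha (log-uniform).
    """

    model_kind: str = "elastic_net_lr"  # or "random_forest"
    c_range: tuple[float, float] = (1e-4, 1e4)
    l1_ratio_range: tuple[float, float] = (0.0, 1.0)
    min_leaf_range: tuple[int, int] = (1, 50)
    n_estimators_range: tuple[int, int] = (50, 500)
    max_depth_range: tuple[int, int] = (2, 32)
    ccp_alpha_range: tuple[float, float] = (1e-6, 1e-1)
    search_budget: int = 50

    def __post_init__(self):
        if self.model_kind not in ("elastic_net_lr", "random_forest"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.search_budget < 1:
            raise ValueError("search_budget must be >= 1")
        for name in ("c_range", "l1_ratio_range", "ccp_alpha_range",
                     "min_leaf_range", "n_estimators_range", "max_depth_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered")

    def sample(self, rng: np.random.Generator) -> dict:
        if self.model_kind == "elastic_net_lr":
            return {
                "C": float(np.exp(rng.uniform(*np.log(self.c_range)))),
                "l1_ratio": float(rng.uniform(*self.l1_ratio_range)),
            }
        return {
            "min_samples_leaf": int(rng.integers(self.min_leaf_range[0],
                                                 self.min_leaf_range[1] + 1)),
            "n_estimators": int(rng.integers(self.n_estimators_range[0],
                                             self.n_estimators_range[1] + 1)),
            "max_depth": int(rng.integers(self.max_depth_range[0],
                                          self.max_depth_range[1] + 1)),
            "ccp_alpha": float(np.exp(rng.uniform(*np.log(self.ccp_alpha_range)))),
        }

    def candidates(self, seed, budget: int | None = None) -> list[dict]:
        """Seeded prefix stream: budget b yields the first b of budget b' > b."""
        rng = np.random.default_rng(seed)
        return [self.sample(rng) for _ in range(budget or self.search_budget)]


def make_estimator(model_kind: str, params: dict, seed: int = 0):
    if model_kind == "elastic_net_lr":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "lr",
                    # elastic net via saga; tol/max_iter trade a little
                    # optimizer precision for wall time on wide count data
                    LogisticRegression(
                        solver="saga", C=params["C"], l1_ratio=params["l1_ratio"],
                        max_iter=2000, tol=1e-3, random_state=seed,
                    ),
                ),
            ]
        )
    if model_kind == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown model_kind {model_kind!r}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def auroc(scores, labels) -> float:
    """Rank-statistic AUROC with average-rank tie handling.

    Equals U/(n_pos * n_neg) for the Mann-Whitney U of positive-class scores
    against negative-class scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = sps.rankdata(s)
    u = float(r[y == 1].sum() - n1 * (n1 + 1) / 2.0)
    return u / (n1 * n0)


def evaluate(scores, labels, cutoff: float | None = None) -> dict:
    """AUROC, AUPRC (step interpolation), and optional cutoff metrics."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    out = {
        "auroc": auroc(s, y),
        "auprc": float(average_precision_score(y, s)),
    }
    if cutoff is not None:
        pred = s >= cutoff
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        out["sensitivity"] = tp / (tp + fn)
        out["specificity"] = tn / (tn + fp)
        out["precision"] = tp / (tp + fp) if tp + fp else float("nan")
    return out


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def youden_cutoff(scores, labels) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Predictions are positive when score >= threshold; candidates are the
    distinct scores plus +inf (predict all negative).  Ties in J break
    toward the higher threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    best = None
    for t in list(np.unique(s)) + [float("inf")]:
        pred = s >= t
        sens = float((pred & (y == 1)).sum()) / n1
        spec = float((~pred & (y == 0)).sum()) / n0
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t > best[1]):
            best = (j, t, sens, spec)
    return CutoffResult(threshold=best[1], sensitivity=best[2], specificity=best[3])


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    fold_index: int
    chosen_hyperparams: dict
    auroc: float
    auprc: float
    youden: CutoffResult
    test_scores: np.ndarray
    test_labels: np.ndarray
    test_index: np.ndarray  # row positions of the outer test set
    best_inner_auroc: float


@dataclass
class CVReport:
    fold_results: list[FoldResult]
    mean_auroc: float
    mean_auprc: float
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    pooled_index: np.ndarray
    config_fingerprint: str
    seed: int
    model_kind: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fold": f.fold_index,
                    "auroc": f.auroc,
                    "auprc": f.auprc,
                    "youden_cutoff": f.youden.threshold,
                    "sensitivity": f.youden.sensitivity,
                    "specificity": f.youden.specificity,
                    **{f"hp_{k}": v for k, v in f.chosen_hyperparams.items()},
                }
                for f in self.fold_results
            ]
        )


def _splitter(k, grouped, seed):
    if grouped:
        return StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def _as_array(X):
    return X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, float)


def nested_cv(
    X,
    y,
    space: HyperparamSpace,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
    groups=None,
) -> CVReport:
    """Nested k-fold cross-validation with budgeted random search.

    For each outer fold, every candidate from the seeded stream is scored by
    mean inner-fold AUROC on the outer-training set only; the best candidate
    (ties to the earliest) is refit on the outer-training set and evaluated
    once on the outer test set.  Outer-test rows never influence the
    hyperparameter choice.  Deterministic for a fixed seed and budget.
    """
    Xa = _as_array(X)
    ya = np.asarray(y).astype(int)
    if k_outer < 2 or k_inner < 2:
        raise ValueError("k_outer and k_inner must be >= 2")
    if len(np.unique(ya)) < 2:
        raise ValueError("stratification requires both classes in y")
    grouped = groups is not None
    ga = np.asarray(groups) if grouped else None

    ss = np.random.SeedSequence(seed)
    fold_seed, cand_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    outer = _splitter(k_outer, grouped, fold_seed)
    split_args = (Xa, ya, ga) if grouped else (Xa, ya)

    folds: list[FoldResult] = []
    for fi, (tr, te) in enumerate(outer.split(*split_args), start=1):
        if len(np.unique(ya[tr])) < 2 or len(np.unique(ya[te])) < 2:
            raise ValueError(f"outer fold {fi} is single-class; stratification failed")
        cands = space.candidates(np.random.SeedSequence([cand_seed, fi]))
        inner = _splitter(k_inner, grouped, fold_seed + fi)
        inner_args = (Xa[tr], ya[tr], ga[tr]) if grouped else (Xa[tr], ya[tr])
        inner_splits = list(inner.split(*inner_args))
        best = None
        for ci, params in enumerate(cands):
            scores = []
            for itr, ite in inner_splits:
                if len(np.unique(ya[tr][itr])) < 2 or len(np.unique(ya[tr][ite])) < 2:
                    raise ValueError("single-class inner fold; increase fold sizes")
                est = make_estimator(space.model_kind, params, seed=fold_seed)
                est.fit(Xa[tr][itr], ya[tr][itr])
                p = est.predict_proba(Xa[tr][ite])[:, 1]
                scores.append(auroc(p, ya[tr][ite]))
            mean_inner = float(np.mean(scores))
            if best is None or mean_inner > best[0]:
                best = (mean_inner, ci, params)
        best_inner, _, best_params = best
        est = make_estimator(space.model_kind, best_params, seed=fold_seed)
        est.fit(Xa[tr], ya[tr])
        p_te = est.predict_proba(Xa[te])[:, 1]
        metrics = evaluate(p_te, ya[te])
        folds.append(
            FoldResult(
                fold_index=fi,
                chosen_hyperparams=best_params,
                auroc=metrics["auroc"],
                auprc=metrics["auprc"],
                youden=youden_cutoff(p_te, ya[te]),
                test_scores=p_te,
                test_labels=ya[te],
                test_index=te,
                best_inner_auroc=best_inner,
            )
        )

    pooled_scores = np.concatenate([f.test_scores for f in folds])
    pooled_labels = np.concatenate([f.test_labels for f in folds])
    pooled_index = np.concatenate([f.test_index for f in folds])
    fp = hashlib.sha1(
        repr((space, k_outer, k_inner, seed, Xa.shape)).encode()
    ).hexdigest()[:12]
    return CVReport(
        fold_results=folds,
        mean_auroc=float(np.mean([f.auroc for f in folds])),
        mean_auprc=float(np.mean([f.auprc for f in folds])),
        pooled_scores=pooled_scores,
        pooled_labels=pooled_labels,
        pooled_index=pooled_index,
        config_fingerprint=fp,
        seed=seed,
        model_kind=space.model_kind,
    )


def median_hyperparams(report: CVReport) -> dict:
    """Per-parameter median across the outer folds (ints stay ints)."""
    keys = report.fold_results[0].chosen_hyperparams.keys()
    out = {}
    for k in keys:
        vals = [f.chosen_hyperparams[k] for f in report.fold_results]
        med = float(np.median(vals))
        out[k] = int(round(med)) if all(isinstance(v, int) for v in vals) else med
    return out


@dataclass
class ImportanceReport:
    ranked: list[tuple[str, float]]  # sorted by |importance| descending
    kind: str  # "lr_coefficient" | "rf_gini"

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.ranked), name=self.kind)


def feature_importance(estimator, kind: str, feature_names) -> ImportanceReport:
    """Signed LR coefficients or normalized RF Gini importances.

    The estimator must already be fitted (conventionally with the median
    hyperparameters across outer folds, refit on all data).  LR coefficients
    are reported on the standardized-feature scale.  RF importances are
    scikit-learn's Gini importances, which sum to 1 across features whenever
    any split was made.
    """
    from sklearn.utils.validation import check_is_fitted

    if kind == "lr_coefficient":
        lr = estimator.named_steps["lr"] if hasattr(estimator, "named_steps") else estimator
        check_is_fitted(lr)
        values = np.asarray(lr.coef_).ravel()
    elif kind == "rf_gini":
        check_is_fitted(estimator)
        values = np.asarray(estimator.feature_importances_)
    else:
        raise ValueError(f"unknown importance kind {kind!r}")
    order = np.argsort(-np.abs(values), kind="stable")
    ranked = [(feature_names[i], float(values[i])) for i in order]
    return ImportanceReport(ranked=ranked, kind=kind)
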