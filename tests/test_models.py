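"""Metrics, Youden cutoffs, nested CV mechanics, importances."""

import numpy as np
import pytest

from chfpheno.keywords import rank_test
from chfpheno.models import (
    CutoffResult,
    HyperparamSpace,
    auroc,
    evaluate,
    feature_importance,
    make_estimator,
    median_hyperparams,
    nested_cv,
    youden_cutoff,
)


def auroc_oracle(scores, labels):
    """O(n^2) pairwise comparison: wins + half ties over pos x neg pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def youden_oracle(scores, labels):
    """Exhaustive search over every candidate cutpoint (>= rule)."""
    s = np.asarray(scores)
    y = np.asarray(labels)
    best_j = -np.inf
    for t in list(np.unique(s)) + [np.inf]:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        best_j = max(best_j, sens + spec - 1)
    return best_j


class TestEvaluate:
    def test_perfect_scores(self):
        m = evaluate([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m["auroc"] == 1.0
        assert m["auprc"] == 1.0

    def test_constant_scores_degenerate(self):
        m = evaluate([0.5] * 10, [0, 0, 0, 0, 0, 0, 0, 1, 1, 1])
        assert m["auroc"] == 0.5
        assert m["auprc"] == pytest.approx(0.3)  # prevalence

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate([0.1, 0.9], [1, 1])

    def test_auroc_matches_pairwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(auroc_oracle(scores, labels))

    def test_auroc_equals_rank_test_u(self, rng):
        counts_pos = rng.poisson(2.0, size=20)
        counts_neg = rng.poisson(1.2, size=30)
        u = rank_test(counts_pos, counts_neg).u_statistic
        scores = np.concatenate([counts_pos, counts_neg]).astype(float)
        labels = np.array([1] * 20 + [0] * 30)
        assert auroc(scores, labels) == pytest.approx(u / (20 * 30))

    def test_cutoff_metrics(self):
        m = evaluate([0.1, 0.6, 0.7, 0.9], [0, 0, 1, 1], cutoff=0.65)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0
        assert m["precision"] == 1.0


class TestYouden:
    def test_perfect_separation(self):
        c = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert c.sensitivity == 1.0 and c.specificity == 1.0 and c.j == 1.0
        assert 0.2 < c.threshold <= 0.8

    def test_fully_inverted_pair(self):
        c = youden_cutoff([0.6, 0.4], [0, 1])
        assert c.j == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            youden_cutoff([0.5, 0.6], [1, 1])

    def test_matches_exhaustive_threshold_search(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 50))
            scores = np.round(rng.random(n), 2)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            c = youden_cutoff(scores, labels)
            assert c.j == pytest.approx(youden_oracle(scores, labels))
            # the reported threshold achieves the reported (sens, spec)
            pred = scores >= c.threshold
            assert (pred & (labels == 1)).sum() / (labels == 1).sum() == pytest.approx(c.sensitivity)

    def test_ties_break_toward_higher_threshold(self):
        # all-negative rule (t=inf) ties J=0 with t=0.4; the higher wins
        c = youden_cutoff([0.6, 0.4], [0, 1])
        assert c.threshold == np.inf


def _planted_matrix(rng, n=240):
    X = rng.poisson(1.0, size=(n, 4)).astype(float)
    y = rng.integers(0, 2, size=n)
    X[:, 0] = y * (2 + rng.poisson(2.0, size=n)) + rng.poisson(0.2, size=n)
    return X, y


class TestNestedCV:
    def space(self, budget=4):
        return HyperparamSpace(search_budget=budget)

    def test_outer_folds_partition_rows(self, rng):
        X, y = _planted_matrix(rng)
        rep = nested_cv(X, y, self.space(), k_outer=5, k_inner=3, seed=1)
        assert len(rep.fold_results) == 5
        idx = np.concatenate([f.test_index for f in rep.fold_results])
        assert sorted(idx.tolist()) == list(range(len(y)))  # disjoint union

    def test_mean_auroc_is_fold_average(self, rng):
        X, y = _planted_matrix(rng)
        rep = nested_cv(X, y, self.space(2), k_outer=3, k_inner=2, seed=1)
        assert rep.mean_auroc == pytest.approx(
            np.mean([f.auroc for f in rep.fold_results]), abs=1e-12
        )

    def test_separable_signal_recovered(self, rng):
        X, y = _planted_matrix(rng)
        # verify linear separability of the planted column on the margin
        assert X[y == 1, 0].min() > X[y == 0, 0].max() - 2
        rep = nested_cv(X, y, self.space(), k_outer=5, k_inner=3, seed=0)
        assert rep.mean_auroc >= 0.99

    def test_null_signal_calibration(self):
        aurocs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(500, 4))
            y = np.array([0, 1] * 250)
            rep = nested_cv(X, y, self.space(2), k_outer=5, k_inner=2, seed=seed)
            aurocs.append(rep.mean_auroc)
        assert 0.4 <= float(np.mean(aurocs)) <= 0.6

    def test_deterministic_given_seed(self, rng):
        X, y = _planted_matrix(rng)
        a = nested_cv(X, y, self.space(2), k_outer=3, k_inner=2, seed=5)
        b = nested_cv(X, y, self.space(2), k_outer=3, k_inner=2, seed=5)
        assert a.mean_auroc == b.mean_auroc
        assert [f.chosen_hyperparams for f in a.fold_results] == [
            f.chosen_hyperparams for f in b.fold_results
        ]

    def test_single_class_fails_before_fitting(self):
        with pytest.raises(ValueError, match="both classes"):
            nested_cv(np.zeros((10, 2)), np.ones(10), self.space())

    def test_budget_monotonicity(self, rng):
        X, y = _planted_matrix(rng, n=160)
        best = {}
        for budget in (3, 8):
            rep = nested_cv(X, y, self.space(budget), k_outer=3, k_inner=2, seed=7)
            best[budget] = [f.best_inner_auroc for f in rep.fold_results]
        for b3, b8 in zip(best[3], best[8]):
            assert b8 >= b3 - 1e-12

    def test_grouped_folds_keep_patients_together(self, rng):
        n = 200
        X, y0 = _planted_matrix(rng, n=n)
        groups = np.repeat([f"p{i}" for i in range(n // 2)], 2)
        y = np.repeat(y0[: n // 2], 2)  # labels agree within patient
        rep = nested_cv(X, y, self.space(2), k_outer=4, k_inner=2, seed=2, groups=groups)
        for f in rep.fold_results:
            test_patients = set(groups[f.test_index])
            train_idx = np.setdiff1d(np.arange(n), f.test_index)
            assert test_patients.isdisjoint(set(groups[train_idx]))

    def test_outer_test_rows_never_seen_during_search(self, rng, monkeypatch):
        """Fold-membership audit: every estimator fitted before the final
        per-fold refit must train on rows disjoint from that fold's test set."""
        import chfpheno.models as M

        X, y = _planted_matrix(rng, n=120)
        X[:, 1] = np.arange(120)  # row-identifying beacon column
        fits = []
        real = make_estimator

        def spy(kind, params, seed=0):
            est = real(kind, params, seed)
            orig_fit = est.fit

            def fit(Xf, yf):
                fits.append(set(np.asarray(Xf)[:, 1].astype(int)))
                return orig_fit(Xf, yf)

            est.fit = fit
            return est

        monkeypatch.setattr(M, "make_estimator", spy)
        rep = M.nested_cv(X, y, self.space(2), k_outer=3, k_inner=2, seed=3)
        per_fold = 2 * 2 + 1  # budget x k_inner + final refit
        for i, f in enumerate(rep.fold_results):
            test_rows = set(f.test_index.tolist())
            fold_fits = fits[i * per_fold : (i + 1) * per_fold]
            for rows in fold_fits[:-1]:  # all search fits
                assert rows.isdisjoint(test_rows)


class TestImportance:
    def test_rf_gini_sums_to_one(self, rng):
        X, y = _planted_matrix(rng)
        rf = make_estimator("random_forest",
                            {"min_samples_leaf": 2, "n_estimators": 60,
                             "max_depth": 6, "ccp_alpha": 1e-6}, seed=0)
        rf.fit(X, y)
        rep = feature_importance(rf, "rf_gini", ["f0", "f1", "f2", "f3"])
        assert sum(v for _, v in rep.ranked) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for _, v in rep.ranked)

    def test_planted_signal_has_top_positive_coefficient(self, rng):
        X, y = _planted_matrix(rng)
        lr = make_estimator("elastic_net_lr", {"C": 1.0, "l1_ratio": 0.5}, seed=0)
        lr.fit(X, y)
        rep = feature_importance(lr, "lr_coefficient", ["planted", "a", "b", "c"])
        name, value = rep.ranked[0]
        assert name == "planted" and value > 0

    def test_infinite_penalty_zeroes_importances(self, rng):
        X, y = _planted_matrix(rng)
        lr = make_estimator("elastic_net_lr", {"C": 1e-10, "l1_ratio": 1.0}, seed=0)
        lr.fit(X, y)
        rep = feature_importance(lr, "lr_coefficient", ["f0", "f1", "f2", "f3"])
        assert all(v == 0 for _, v in rep.ranked)

    def test_unfitted_model_rejected(self):
        lr = make_estimator("elastic_net_lr", {"C": 1.0, "l1_ratio": 0.5})
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            feature_importance(lr, "lr_coefficient", ["a"])

    def test_median_hyperparams_preserve_ints(self, rng):
        X, y = _planted_matrix(rng, n=150)
        space = HyperparamSpace(model_kind="random_forest", search_budget=2,
                                n_estimators_range=(10, 30), max_depth_range=(2, 6))
        rep = nested_cv(X, y, space, k_outer=3, k_inner=2, seed=1)
        med = median_hyperparams(rep)
        assert isinstance(med["n_estimators"], int)
        assert isinstance(med["ccp_alpha"], float)


def test_hyperparam_space_validation():
    with pytest.raises(ValueError, match="model_kind"):
        HyperparamSpace(model_kind="svm")
    with pytest.raises(ValueError, match="search_budget"):
        HyperparamSpace(search_budget=0)
    with pytest.raises(ValueError, match="ordered"):
        HyperparamSpace(c_range=(10.0, 1.0))
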