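"""Population error extrapolation, bootstrap CIs, cross-site validation."""

import numpy as np
import pytest

from chfpheno.cohort import ScreeningGroup
from chfpheno.datasets import screening_error_table
from chfpheno.evaluation import (
    CIConfig,
    GroupErrorTable,
    GroupStats,
    bootstrap_ci,
    classify_random_sample,
    cross_site_eval,
    estimate_population_error,
)
from chfpheno.synth_ehr import generate_cohort
from tests.conftest import make_config

G = list(ScreeningGroup)


def table_from(rows):
    return GroupErrorTable(groups={g: GroupStats(*r) for g, r in zip(G, rows)})


class TestPopulationError:
    def test_reference_counts_give_1_6_percent(self):
        est = estimate_population_error(screening_error_table())
        assert round(est.value, 3) == 0.016
        assert round(100 * est.value, 1) == 1.6

    def test_zero_errors_give_zero(self):
        t = table_from([(0, 700, 14, 140), (0, 350, 4, 41), (0, 1050, 3, 342), (0, 700, 1, 477)])
        assert estimate_population_error(t).value == 0.0

    def test_uniform_error_rate_factorizes(self):
        # error rate 0.1 in every group => estimate = 0.1 * sum(prevalences)
        t = table_from([(10, 100, 20, 100), (10, 100, 10, 100), (10, 100, 5, 100), (10, 100, 1, 100)])
        est = estimate_population_error(t)
        assert est.value == pytest.approx(0.1 * (0.20 + 0.10 + 0.05 + 0.01))
        assert est.prevalence_weight_total == pytest.approx(0.36)

    def test_contributions_sum_to_value(self):
        est = estimate_population_error(screening_error_table())
        assert est.value == pytest.approx(sum(est.per_group_contributions.values()), abs=1e-12)

    def test_monotone_in_counts(self):
        base = estimate_population_error(screening_error_table()).value
        for g in G:
            for attr in ("error_count", "positive_count"):
                t = screening_error_table()
                setattr(t.groups[g], attr, getattr(t.groups[g], attr) + 1)
                assert estimate_population_error(t).value >= base

    def test_zero_denominator_rejected(self):
        t = table_from([(0, 0, 1, 10), (0, 10, 1, 10), (0, 10, 1, 10), (0, 10, 1, 10)])
        with pytest.raises(ValueError, match="zero annotated"):
            estimate_population_error(t)

    def test_count_overflow_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            estimate_population_error(table_from([(11, 10, 1, 10)] * 4))

    def test_csv_round_trip(self, tmp_path):
        t = screening_error_table()
        path = tmp_path / "table.csv"
        t.to_frame().to_csv(path, index=False)
        t2 = GroupErrorTable.from_csv(path)
        assert estimate_population_error(t2).value == estimate_population_error(t).value


class TestBootstrapCI:
    def test_perfect_separation_is_degenerate(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        assert bootstrap_ci(scores, labels, config=CIConfig(n_boot=50)) == (1.0, 1.0, 1.0)

    def test_single_resample_collapses_interval(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:5] = 1
        labels[5:10] = 0
        point, lo, hi = bootstrap_ci(scores, labels, config=CIConfig(n_boot=1, seed=3))
        assert lo == hi

    def test_deterministic_given_seed(self, rng):
        scores = rng.random(60)
        labels = (scores + rng.normal(0, 0.4, 60) > 0.5).astype(int)
        a = bootstrap_ci(scores, labels, config=CIConfig(n_boot=100, seed=9))
        b = bootstrap_ci(scores, labels, config=CIConfig(n_boot=100, seed=9))
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            bootstrap_ci([0.5, 0.6], [1, 1])

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (100, 400, 1600):
            rng = np.random.default_rng(17)
            y = (rng.random(n) < 0.4).astype(int)
            s = rng.normal(y * 1.0, 1.0)
            _, lo, hi = bootstrap_ci(s, y, config=CIConfig(n_boot=200, seed=1))
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_patient_cluster_bootstrap(self, rng):
        n = 80
        pids = np.repeat([f"p{i}" for i in range(n // 2)], 2)
        y = np.repeat(rng.integers(0, 2, n // 2), 2)
        s = rng.normal(y * 1.0, 1.0)
        cfg = CIConfig(n_boot=50, seed=2, unit="patient")
        point, lo, hi = bootstrap_ci(s, y, config=cfg, patient_ids=pids)
        assert lo <= point <= hi
        with pytest.raises(ValueError, match="patient_ids"):
            bootstrap_ci(s, y, config=cfg)

    def test_auprc_metric_supported(self, rng):
        y = rng.integers(0, 2, 60)
        y[:3] = 1
        y[3:6] = 0
        s = rng.random(60)
        point, lo, hi = bootstrap_ci(s, y, metric="auprc", config=CIConfig(n_boot=50))
        assert 0 <= lo <= point <= hi <= 1


class _OracleClassifier:
    """Stand-in fitted pipeline that returns the generator's truth labels."""

    threshold = 0.5

    def __init__(self, truth):
        self.truth = truth

    def classify(self, notes, records):
        return np.array([int(self.truth[n.note_id] == "positive") for n in notes])


class TestClassifyRandomSample:
    def test_oracle_classifier_recovers_generator_truth(self):
        cohort = generate_cohort(make_config(n_patients=200, seed=5))
        table = classify_random_sample(
            cohort.notes(), cohort.records, _OracleClassifier(cohort.truth_labels)
        )
        for g in G:
            pids = [p for p, gg in cohort.group_assignments.items() if gg is g]
            truth_pos = sum(cohort.truth_labels[f"{p}-n0"] == "positive" for p in pids)
            assert table.groups[g].n_random == len(pids)
            assert table.groups[g].positive_count == truth_pos

    def test_zero_prevalence_gives_zero_positives(self):
        cfg = make_config(
            n_patients=100,
            positive_prevalence_per_group={g: 0.0 for g in G},
            seed=6,
        )
        cohort = generate_cohort(cfg)
        table = classify_random_sample(
            cohort.notes(), cohort.records, _OracleClassifier(cohort.truth_labels)
        )
        assert all(st.positive_count == 0 for st in table.groups.values())

    def test_group_sizes_within_three_multinomial_se(self):
        from chfpheno.synth_ehr import GeneratorConfig

        cohort = generate_cohort(
            GeneratorConfig(n_patients=1000, note_length_range=(300, 900), seed=8)
        )
        table = classify_random_sample(
            cohort.notes(), cohort.records, _OracleClassifier(cohort.truth_labels)
        )
        weights = cohort.config.group_weights
        for g in G:
            p = weights[g]
            se = np.sqrt(1000 * p * (1 - p))
            assert abs(table.groups[g].n_random - 1000 * p) <= 3 * se

    def test_unfitted_pipeline_rejected(self):
        class Unfitted:
            threshold = None

        with pytest.raises(ValueError, match="threshold"):
            classify_random_sample([], [], Unfitted())


class TestCrossSite:
    def _two_site(self, seed):
        cfg = make_config(n_patients=300, seed=seed)
        cohort = generate_cohort(cfg)
        labels = cohort.labels01()
        out = {}
        for site in ("MGH", "BIDMC"):
            recs = [r for r in cohort.records if r.notes[0].site == site]
            notes = [n for r in recs for n in r.notes]
            out[site] = (notes, recs)
        return out, labels

    def test_patient_overlap_rejected(self):
        sites, labels = self._two_site(1)
        notes, recs = sites["MGH"]
        with pytest.raises(ValueError, match="overlap"):
            cross_site_eval(notes, recs, labels, notes, recs, labels)

    def test_single_class_test_site_rejected(self):
        sites, labels = self._two_site(1)
        tr_notes, tr_recs = sites["MGH"]
        te_notes, te_recs = sites["BIDMC"]
        all_neg = {k: 0 for k in labels}
        with pytest.raises(ValueError, match="single class"):
            cross_site_eval(tr_notes, tr_recs, labels, te_notes, te_recs, all_neg)

    def test_training_vocabulary_is_closed(self):
        """A phrase unique to the test site contributes no feature column."""
        from chfpheno.pipeline import PipelineConfig, fit_pipeline

        sites, labels = self._two_site(2)
        tr_notes, tr_recs = sites["MGH"]
        cfg = PipelineConfig(discover=False)
        cfg.space.search_budget = 2
        fitted = fit_pipeline(tr_notes, tr_recs, labels, cfg, seed=0)
        cols_before = list(fitted.feature_columns)
        te_notes, te_recs = sites["BIDMC"]
        spiked = te_notes[0].__class__(
            te_notes[0].note_id, te_notes[0].patient_id, te_notes[0].site,
            te_notes[0].date, te_notes[0].text + " zebrafish neverlexiconized phrase.",
        )
        p = fitted.predict_proba([spiked] + te_notes[1:], te_recs)
        assert fitted.feature_columns == cols_before
        assert len(p) == len(te_notes)

    def test_cross_site_matches_within_site_cv(self):
        """Identical generating processes at both sites: external performance
        should track the internal cross-validated estimate."""
        from chfpheno.models import HyperparamSpace, nested_cv
        from chfpheno.pipeline import PipelineConfig, build_features, build_lexicon

        cross, within = [], []
        for seed in range(10):
            sites, labels = self._two_site(100 + seed)
            tr_notes, tr_recs = sites["MGH"]
            te_notes, te_recs = sites["BIDMC"]
            cfg = PipelineConfig(
                discover=False, space=HyperparamSpace(search_budget=3), k_inner=3
            )
            res = cross_site_eval(
                tr_notes, tr_recs, labels, te_notes, te_recs, labels,
                config=cfg, seed=seed, ci_config=CIConfig(n_boot=10, seed=seed),
            )
            cross.append(res["auroc"])
            lex = build_lexicon(tr_notes, tr_recs, cfg)
            fm = build_features(tr_notes, tr_recs, lex, cfg, labels=labels)
            rep = nested_cv(
                fm.frame, fm.labels.to_numpy(), cfg.space, k_outer=5, k_inner=3,
                seed=seed, groups=[n.patient_id for n in tr_notes],
            )
            within.append(rep.mean_auroc)
        assert abs(float(np.mean(cross)) - float(np.mean(within))) <= 0.05


class TestAlternativeWeighting:
    def test_group_share_weights_sum_to_one(self):
        est = estimate_population_error(screening_error_table(), weighting="group_share")
        assert est.prevalence_weight_total == pytest.approx(1.0)
        # weighting each group's error rate by its share of the random
        # sample gives a much higher figure than the published form
        assert 0.07 < est.value < 0.10

    def test_unknown_weighting_rejected(self):
        with pytest.raises(ValueError, match="weighting"):
            estimate_population_error(screening_error_table(), weighting="uniform")
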