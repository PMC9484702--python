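"""Splitting, confusion metrics, ROC/AUC and the multi-method benchmark."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alleracc.descriptors import load_e_descriptor_table
from alleracc.evaluation import (ConfusionCounts, EvaluationReport, benchmark,
                                 compute_metrics, confusion_counts,
                                 f1_from_precision_recall, roc_and_auc,
                                 stratified_split)
from alleracc.models import ClassifierSpec
from alleracc.synthetic import SyntheticParams, generate_dataset


def concordance_auc(y_true, scores):
    """Oracle: tie-corrected all-pairs concordance probability."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestStratifiedSplit:
    def test_80_20_per_class(self):
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        split = stratified_split(y, ratio=0.8, seed=0)
        assert len(split.train_indices) == 160 and len(split.test_indices) == 40
        for cls in (0, 1):
            assert np.sum(y[split.train_indices] == cls) == 80
            assert np.sum(y[split.test_indices] == cls) == 20

    def test_deterministic_per_seed(self):
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        a = stratified_split(y, seed=5)
        b = stratified_split(y, seed=5)
        assert np.array_equal(a.train_indices, b.train_indices)
        assert np.array_equal(a.test_indices, b.test_indices)

    def test_small_classes_floor_to_feasible_split(self):
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        split = stratified_split(y, ratio=0.8, seed=1)
        for cls in (0, 1):
            assert np.sum(y[split.train_indices] == cls) == 4
            assert np.sum(y[split.test_indices] == cls) == 1

    def test_union_covers_everything_disjointly(self):
        y = np.r_[np.zeros(23, int), np.ones(31, int)]
        split = stratified_split(y, seed=2)
        combined = np.sort(np.r_[split.train_indices, split.test_indices])
        assert np.array_equal(combined, np.arange(54))

    def test_class_with_single_sample_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 0, 0, 1]))


class TestConfusionAndMetrics:
    def test_enumeration_example(self):
        counts = confusion_counts([1, 1, 0, 0], [1, 0, 0, 1])
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 1, 1, 1)

    def test_identical_vectors_no_errors(self):
        counts = confusion_counts([1, 0, 1], [1, 0, 1])
        assert counts.fp == 0 and counts.fn == 0

    def test_all_positive_predictions(self):
        counts = confusion_counts([1, 0, 0, 0], [1, 1, 1, 1])
        assert counts.tn == 0 and counts.fp == 3

    def test_string_labels_accepted_with_allergen_positive(self):
        counts = confusion_counts(["allergen", "non_allergen"],
                                  ["allergen", "allergen"])
        assert counts.tp == 1 and counts.fp == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion_counts([1, 0], [1])

    def test_perfect_classifier(self):
        row = compute_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert row.accuracy == row.precision == row.recall == row.f1 == 1.0

    def test_metric_formulas(self):
        row = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        assert row.accuracy == pytest.approx(0.7)
        assert row.precision == pytest.approx(0.75)
        assert row.recall == pytest.approx(0.6)
        assert row.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_degenerate_ratios_flagged_not_raised(self):
        row = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
        assert row.precision == 0.0 and row.f1 == 0.0
        assert "precision" in row.degenerate

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=0))

    @pytest.mark.parametrize("precision, recall, printed_f1", [
        (0.95, 0.85, 0.90),
        (0.91, 0.91, 0.91),
        (0.79, 0.75, 0.77),
        (0.49, 1.00, 0.66),
        (0.80, 0.71, 0.75),
    ])
    def test_harmonic_mean_matches_benchmark_table_rows(self, precision, recall,
                                                        printed_f1):
        assert round(f1_from_precision_recall(precision, recall), 2) == printed_f1


class TestROC:
    def test_perfect_separation_auc_one(self):
        roc = roc_and_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert roc.auc == 1.0

    def test_all_tied_scores_auc_half(self):
        roc = roc_and_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert roc.auc == 0.5

    def test_three_of_four_pairs_concordant(self):
        roc = roc_and_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3])
        assert roc.auc == 0.75

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        roc = roc_and_auc(y, rng.random(50))
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_trapezoid_equals_concordance_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            # discretized scores so ties actually occur
            scores = np.round(rng.random(n), 1)
            roc = roc_and_auc(y, scores)
            assert roc.auc == pytest.approx(concordance_auc(y, scores), abs=1e-12)

    @given(shift=st.floats(min_value=-5, max_value=5),
           scale=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=30, derandomize=True)
    def test_auc_invariant_under_monotone_transform(self, shift, scale):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        scores = rng.random(60)
        base = roc_and_auc(y, scores).auc
        assert roc_and_auc(y, scale * scores + shift).auc == pytest.approx(
            base, abs=1e-12)

    def test_negating_scores_complements_auc(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        scores = rng.random(80)
        assert roc_and_auc(y, -scores).auc == pytest.approx(
            1.0 - roc_and_auc(y, scores).auc, abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([1, 1, 1], [0.1, 0.2, 0.3])


@pytest.fixture(scope="module")
def small_report():
    dataset = generate_dataset(SyntheticParams(
        n_per_class=80, length_range=(30, 80), seed=21))
    specs = [ClassifierSpec(kind=k, seed=21,
                            hyperparams={"epochs": 5} if k == "lstm" else {})
             for k in ("gaussian_nb", "extra_trees", "lstm")]
    return benchmark(dataset, specs, load_e_descriptor_table(), seed=21)


class TestBenchmark:

    def test_one_row_per_spec_with_shared_split(self, small_report):
        assert [r.kind for r in small_report.results] == [
            "gaussian_nb", "extra_trees", "lstm"]
        assert small_report.split["n_train"] == 128
        assert small_report.split["n_test"] == 32

    def test_report_json_round_trip(self, small_report, tmp_path):
        path = tmp_path / "report.json"
        small_report.to_json(path)
        back = EvaluationReport.from_json(path)
        assert back.best_method == small_report.best_method
        for orig, loaded in zip(small_report.results, back.results):
            assert loaded.kind == orig.kind
            assert loaded.auc == pytest.approx(orig.auc)
            assert loaded.test_metrics.f1 == pytest.approx(orig.test_metrics.f1)

    def test_text_report_lists_every_method(self, small_report):
        text = small_report.to_text()
        for kind in ("gaussian_nb", "extra_trees", "lstm"):
            assert kind in text

    def test_roc_points_retained_for_best_method(self, small_report):
        fpr = small_report.roc_points["fpr"]
        tpr = small_report.roc_points["tpr"]
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0

    def test_rerun_with_same_seeds_is_identical(self):
        dataset = generate_dataset(SyntheticParams(
            n_per_class=40, length_range=(30, 60), seed=22))
        specs = [ClassifierSpec(kind="gaussian_nb", seed=22)]
        table = load_e_descriptor_table()
        a = benchmark(dataset, specs, table, seed=22)
        b = benchmark(dataset, specs, table, seed=22)
        assert a.results[0].auc == b.results[0].auc
        assert a.results[0].test_metrics == b.results[0].test_metrics
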