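import json

import numpy as np
import pytest

from lungct.errors import ValidationError
from lungct.manifest import CLASS_NAMES
from lungct.metrics import (
    classwise_accuracy,
    compute_metrics,
    confusion,
    render_report,
    report_to_dict,
)

#: Confusion counts of the published held-out evaluation (450 images):
#: Benign row 146/1/3, Malignant 6/140/4, Normal 5/0/145.
CANONICAL_CM = np.array([[146, 1, 3], [6, 140, 4], [5, 0, 145]])


def cm_to_label_lists(cm):
    true, pred = [], []
    for i, t in enumerate(CLASS_NAMES):
        for j, p in enumerate(CLASS_NAMES):
            true += [t] * int(cm[i, j])
            pred += [p] * int(cm[i, j])
    return true, pred


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion(list(CLASS_NAMES), list(CLASS_NAMES))
        assert np.array_equal(cm, np.eye(3, dtype=int))

    def test_empty_lists_give_zero_matrix(self):
        assert confusion([], []).sum() == 0

    def test_reconstructed_narrative_counts(self):
        true, pred = cm_to_label_lists(CANONICAL_CM)
        assert np.array_equal(confusion(true, pred), CANONICAL_CM)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion(["Benign"], [])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion(["Benign"], ["Weird"])


class TestComputeMetrics:
    def test_canonical_counts_reproduce_published_values(self):
        report = compute_metrics(CANONICAL_CM)
        assert round(100 * report.accuracy, 1) == 95.8
        b = report.per_class["Benign"]
        assert (round(100 * b.precision, 1), round(100 * b.recall, 1),
                round(100 * b.f1, 1)) == (93.0, 97.3, 95.1)
        m = report.per_class["Malignant"]
        assert (round(100 * m.precision, 1), round(100 * m.recall, 1),
                round(100 * m.f1, 1)) == (99.3, 93.3, 96.2)
        n = report.per_class["Normal"]
        assert (round(100 * n.precision, 1), round(100 * n.recall, 1),
                round(100 * n.f1, 1)) == (95.4, 96.7, 96.0)

    def test_diagonal_matrix_scores_ones(self):
        report = compute_metrics(np.diag([10, 10, 10]))
        assert report.accuracy == 1.0
        for m in report.per_class.values():
            assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_agrees_with_per_sample_brute_force(self):
        """100 random matrices against an explicit per-sample tally."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            cm = rng.integers(0, 40, (3, 3))
            if cm.sum() == 0:
                cm[0, 0] = 1
            true, pred = cm_to_label_lists(cm)
            report = compute_metrics(cm)
            correct = sum(t == p for t, p in zip(true, pred))
            assert abs(report.accuracy - correct / len(true)) < 1e-12
            for name in CLASS_NAMES:
                tp = sum(1 for t, p in zip(true, pred) if t == name and p == name)
                fp = sum(1 for t, p in zip(true, pred) if t != name and p == name)
                fn = sum(1 for t, p in zip(true, pred) if t == name and p != name)
                m = report.per_class[name]
                assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
                if tp + fp:
                    assert abs(m.precision - tp / (tp + fp)) < 1e-12
                if tp + fn:
                    assert abs(m.recall - tp / (tp + fn)) < 1e-12
                if m.precision + m.recall:
                    f1 = 2 * m.precision * m.recall / (m.precision + m.recall)
                    assert abs(m.f1 - f1) < 1e-12

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(1)
        for _ in range(20):
            cm = rng.integers(1, 30, (3, 3))
            true, pred = cm_to_label_lists(cm)
            report = compute_metrics(cm)
            p, r, f, _ = precision_recall_fscore_support(
                true, pred, labels=list(CLASS_NAMES), zero_division=0
            )
            for k, name in enumerate(CLASS_NAMES):
                m = report.per_class[name]
                assert abs(m.precision - p[k]) < 1e-12
                assert abs(m.recall - r[k]) < 1e-12
                assert abs(m.f1 - f[k]) < 1e-12

    def test_one_vs_rest_counts_partition_total(self):
        report = compute_metrics(CANONICAL_CM)
        for m in report.per_class.values():
            assert m.tp + m.fp + m.fn + m.tn == report.total

    def test_zero_denominator_flagged_not_nan(self):
        cm = np.array([[0, 5, 0], [0, 10, 0], [0, 5, 0]])
        report = compute_metrics(cm)
        b = report.per_class["Benign"]
        assert b.undefined and b.precision == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(np.zeros((3, 3), dtype=int))


class TestClasswiseAccuracy:
    def test_published_classwise_accuracies(self):
        cw = classwise_accuracy(CANONICAL_CM)
        assert round(100 * cw["Benign"], 2) == 97.33
        assert round(100 * cw["Malignant"], 2) == 93.33
        assert round(100 * cw["Normal"], 2) == 96.67

    def test_diagonal_gives_unit_accuracy(self):
        assert classwise_accuracy(np.diag([5, 5, 5])) == {c: 1.0 for c in CLASS_NAMES}

    def test_equals_per_class_recall(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            cm = rng.integers(1, 25, (3, 3))
            cw = classwise_accuracy(cm)
            report = compute_metrics(cm)
            for name in CLASS_NAMES:
                assert cw[name] == report.per_class[name].recall

    def test_empty_row_flagged_as_none(self):
        cm = np.array([[0, 0, 0], [0, 5, 0], [0, 0, 5]])
        assert classwise_accuracy(cm)["Benign"] is None


class TestRenderReport:
    def test_text_report_carries_headline_accuracy(self):
        report = compute_metrics(CANONICAL_CM)
        text = render_report(report, CANONICAL_CM)
        assert "95.8" in text
        assert "97.33" in text  # class-wise accuracy at two decimals

    def test_undefined_metrics_render_as_na(self):
        cm = np.array([[0, 5, 0], [0, 10, 0], [0, 5, 0]])
        text = render_report(compute_metrics(cm), cm)
        assert "n/a" in text

    def test_json_round_trip_preserves_numbers(self):
        report = compute_metrics(CANONICAL_CM)
        parsed = json.loads(render_report(report, CANONICAL_CM, as_json=True))
        assert parsed == report_to_dict(report, CANONICAL_CM)

    def test_micro_recall_equals_accuracy_on_balanced_design(self):
        report = compute_metrics(CANONICAL_CM)
        tp_sum = sum(m.tp for m in report.per_class.values())
        fn_sum = sum(m.fn for m in report.per_class.values())
        assert abs(tp_sum / (tp_sum + fn_sum) - report.accuracy) < 1e-12

    def test_confusion_total_equals_sample_count(self):
        true, pred = cm_to_label_lists(CANONICAL_CM)
        cm = confusion(true, pred)
        assert cm.sum() == len(true) == 450
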