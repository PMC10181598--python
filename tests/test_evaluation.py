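import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import eogwave as ew
from eogwave.evaluation import (
    ConfusionCounts,
    SplitSpec,
    binary_counts,
    confusion_matrix,
    derived_metrics,
    jaccard_index,
    roc_curve,
    split_indices,
)
from eogwave.worked_examples import (
    CONSISTENT_ROWS,
    PRINTED_METRICS,
    rederive_metrics,
)

label_pairs = st.integers(2, 60).flatmap(
    lambda n: st.tuples(
        hnp.arrays(int, n, elements=st.integers(0, 4)),
        hnp.arrays(int, n, elements=st.integers(0, 4)),
    )
)


class TestSplit:
    def test_default_matrix_splits_406_102(self, default_features):
        train, test = ew.train_test_split(default_features, SplitSpec())
        assert train.n_windows == 406
        assert test.n_windows == 102
        # stratification: per-class train share within one row of 80%
        for c in range(5):
            n_c = np.sum(default_features.window_labels == c)
            got = np.sum(train.window_labels == c)
            assert abs(got - 0.8 * n_c) <= 1.0

    def test_two_rows_per_class_at_half_fraction(self):
        matrix = ew.FeatureMatrix(
            np.arange(40.0).reshape(10, 4),
            np.repeat([0, 1, 2, 3, 4], 2),
            feature_names=tuple("abcd"),
        )
        train, test = ew.train_test_split(matrix, SplitSpec(0.5, seed=1))
        assert np.bincount(train.window_labels).tolist() == [1] * 5
        assert np.bincount(test.window_labels).tolist() == [1] * 5

    def test_same_seed_reproduces_partition(self, default_features):
        a = split_indices(default_features.window_labels, SplitSpec(seed=4))
        b = split_indices(default_features.window_labels, SplitSpec(seed=4))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_partition_is_disjoint_and_complete(self, default_features):
        train, test = split_indices(default_features.window_labels, SplitSpec())
        union = np.sort(np.concatenate([train, test]))
        assert np.array_equal(union, np.arange(default_features.n_windows))

    def test_thin_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_indices(np.array([0, 0, 1]), SplitSpec())

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([0, 1, 2, 2, 1])
        grid = confusion_matrix(y, y, 3)
        assert np.array_equal(grid, np.diag([1, 2, 2]))

    def test_collapsed_prediction_is_single_column(self):
        y = np.array([0, 1, 2, 3, 4])
        grid = confusion_matrix(y, np.zeros(5, dtype=int), 5)
        assert grid[:, 0].sum() == 5 and grid[:, 1:].sum() == 0

    def test_matches_loop_tally_oracle(self, rng):
        y_true = rng.integers(0, 5, 100)
        y_pred = rng.integers(0, 5, 100)
        grid = confusion_matrix(y_true, y_pred, 5)
        tally = np.zeros((5, 5), dtype=int)
        for t, p in zip(y_true, y_pred):
            tally[t, p] += 1
        assert np.array_equal(grid, tally)
        assert grid.sum() == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)


class TestBinaryCounts:
    def test_diagonal_grid_has_no_errors(self):
        counts = binary_counts(np.diag([3, 4, 5]), 1)
        assert counts.FP == 0 and counts.FN == 0
        assert counts.TP == 4 and counts.TN == 8

    def test_single_column_grid_has_zero_tn_for_that_class(self):
        grid = np.zeros((3, 3), dtype=int)
        grid[:, 0] = [2, 3, 4]
        counts = binary_counts(grid, 0)
        assert counts.TN == 0 and counts.FP == 7

    def test_matches_summation_oracle(self, rng):
        grid = rng.integers(0, 20, (5, 5))
        for c in range(5):
            counts = binary_counts(grid, c)
            assert counts.TP == grid[c, c]
            assert counts.FN == grid[c].sum() - grid[c, c]
            assert counts.FP == grid[:, c].sum() - grid[c, c]
            assert counts.TP + counts.TN + counts.FP + counts.FN == grid.sum()

    def test_class_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binary_counts(np.eye(3, dtype=int), 3)


class TestDerivedMetrics:
    def test_published_rows_rederive_to_printed_precision(self):
        """The consistent published per-feature rows reproduce their printed
        sensitivity/specificity/precision from the raw counts."""
        for name in CONSISTENT_ROWS:
            row = rederive_metrics(name)
            sens, spec, prec = PRINTED_METRICS[name]
            assert row.sensitivity == pytest.approx(sens, abs=0.02)
            assert row.specificity == pytest.approx(spec, abs=0.02)
            assert row.precision == pytest.approx(prec, abs=0.02)

    def test_vertical_amplitude_row(self):
        row = derived_metrics(ConfusionCounts(1, 75.76, 0.103, 2.7607))
        assert row.sensitivity == pytest.approx(26.59, abs=0.01)
        assert row.specificity == pytest.approx(99.86, abs=0.01)
        assert row.precision == pytest.approx(90.66, abs=0.01)

    def test_horizontal_covariance_row(self):
        row = derived_metrics(ConfusionCounts(1, 16.05, 2.5, 0.6645))
        assert row.specificity == pytest.approx(86.52, abs=0.01)
        assert row.precision == pytest.approx(28.57, abs=0.01)

    def test_error_free_counts_give_all_hundred(self):
        row = derived_metrics(ConfusionCounts(10, 90, 0, 0))
        assert (
            row.sensitivity == row.specificity == row.accuracy == row.precision == 100.0
        )

    def test_zero_denominator_marked_undefined(self):
        row = derived_metrics(ConfusionCounts(0, 5, 0, 0))
        assert row.precision is None and row.sensitivity is None
        assert row.specificity == 100.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 1, 1, 1)


class TestROC:
    def test_perfect_scores(self):
        truth = np.array([0, 1, 2, 0, 1])
        onehot = np.eye(3)[truth]
        curve = roc_curve(onehot, truth)
        assert curve.auc == pytest.approx(1.0)
        assert curve.sensitivity_at_half == pytest.approx(100.0)

    def test_inverted_scores(self):
        truth = np.array([0, 1, 2, 0, 1])
        curve = roc_curve(1.0 - np.eye(3)[truth], truth)
        assert curve.auc == pytest.approx(0.0)

    def test_constant_scores_give_half_auc(self):
        curve = roc_curve(np.full(10, 0.3), np.tile([0, 1], 5))
        assert curve.auc == pytest.approx(0.5)

    def test_reversing_scores_reflects_auc(self, rng):
        scores = rng.uniform(size=50)
        truth = rng.integers(0, 2, 50)
        a = roc_curve(scores, truth).auc
        b = roc_curve(1.0 - scores, truth).auc
        assert a + b == pytest.approx(1.0)

    def test_monotone_curve(self, rng):
        scores = rng.uniform(size=80)
        truth = rng.integers(0, 2, 80)
        curve = roc_curve(scores, truth)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.2, 0.8]), np.array([1, 1]))


class TestJaccard:
    def test_identical_sequences(self):
        assert jaccard_index([0, 1, 2], [0, 1, 2]) == 1.0
        assert jaccard_index([0, 1, 2], [0, 1, 2], mode="macro") == 1.0

    def test_fully_disjoint_sequences(self):
        assert jaccard_index([0, 0], [1, 1]) == 0.0
        assert jaccard_index([0, 0], [1, 1], mode="macro") == 0.0

    def test_hand_tallied_example(self):
        """truth (0,0,1,1) vs prediction (0,1,1,1): class-0 IoU = 1/2
        (TP=1, FN=1, FP=0), class-1 IoU = 2/3 — micro 3/5, macro 7/12."""
        truth, pred = [0, 0, 1, 1], [0, 1, 1, 1]
        assert jaccard_index(truth, pred) == pytest.approx(3 / 5)
        assert jaccard_index(truth, pred, mode="macro") == pytest.approx(7 / 12)

    @given(pair=label_pairs)
    def test_micro_equals_accuracy_identity(self, pair):
        """For single-label predictions micro-Jaccard is a/(2-a)."""
        y_true, y_pred = pair
        a = float(np.mean(y_true == y_pred))
        assert jaccard_index(y_true, y_pred) == pytest.approx(a / (2 - a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaccard_index([0, 1], [0])


class TestEvaluateAll:
    def test_separable_matrix_classified_perfectly(self, rng):
        """Five widely separated clusters: every classifier must reach
        test Jaccard 1.0."""
        centers = np.arange(5) * 10.0
        X = np.vstack(
            [rng.normal(c, 0.1, size=(30, 3)) for c in centers]
        )
        labels = np.repeat(np.arange(5), 30)
        matrix = ew.FeatureMatrix(X, labels, feature_names=("a", "b", "c"))
        report = ew.evaluate_all(matrix)
        for result in report.algorithms.values():
            assert result.test_jaccard == 1.0
            assert np.array_equal(
                result.confusion, np.diag(np.diag(result.confusion))
            )

    def test_report_is_deterministic(self, small_features):
        a = ew.evaluate_all(small_features).as_dict()
        b = ew.evaluate_all(small_features).as_dict()
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_report_structure(self, small_features):
        report = ew.evaluate_all(small_features)
        assert set(report.algorithms) == {"knn", "svm", "dt"}
        for result in report.algorithms.values():
            assert 0.0 <= result.test_jaccard <= 1.0
            assert 0.0 <= result.roc.auc <= 1.0
            assert result.confusion.sum() == report.n_test
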