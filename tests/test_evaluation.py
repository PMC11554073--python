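"""Temporal split, metrics, repeated CV, ROC averaging, paired comparison."""

import numpy as np
import pandas as pd
import pytest
from datetime import date

from kpsfusion.evaluation import (compute_metrics, mean_roc_curve,
                                  paired_t_test, repeated_cv, temporal_split)


def _frame(n, dates=None):
    return pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "operation_date": dates if dates is not None
        else [date(2001, 1, 1) + pd.Timedelta(days=30 * i) for i in range(n)],
    })


class TestTemporalSplit:
    def test_150_gives_100_50(self):
        train, test = temporal_split(_frame(150))
        assert len(train) == 100 and len(test) == 50
        assert not set(train) & set(test)

    def test_3_gives_2_1(self):
        train, test = temporal_split(_frame(3))
        assert len(train) == 2 and len(test) == 1

    def test_tied_dates_break_by_patient_id(self):
        df = _frame(6, dates=[date(2010, 5, 5)] * 6).sample(frac=1, random_state=0)
        train, test = temporal_split(df)
        assert train == ["P000", "P001", "P002", "P003"]
        assert test == ["P004", "P005"]

    def test_train_precedes_test_in_time(self):
        df = _frame(30).sample(frac=1, random_state=1)
        train, test = temporal_split(df)
        lookup = dict(zip(df["patient_id"], df["operation_date"]))
        assert max(lookup[i] for i in train) <= min(lookup[i] for i in test)


class TestComputeMetrics:
    def test_three_of_four_concordant_pairs(self):
        m = compute_metrics([1, 1, 0, 0], [0.9, 0.3, 0.8, 0.2])
        assert m["auc"] == pytest.approx(0.75)

    def test_perfect_ranking(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m["auc"] == 1.0 and m["accuracy"] == 1.0

    def test_hand_confusion_matrix(self):
        # TP=2 FN=2 FP=1 TN=5 at threshold 0.5
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.3, 0.2, 0.7, 0.1, 0.1, 0.1, 0.1, 0.1]
        m = compute_metrics(labels, scores)
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["f1"] == pytest.approx(2 * 2 / (2 * 2 + 1 + 2))

    def test_ties_count_half(self):
        m = compute_metrics([1, 0], [0.5, 0.5])
        assert m["auc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="AUC"):
            compute_metrics([1, 1], [0.2, 0.4])

    def test_auc_equals_concordant_pair_count(self, rng):
        """Independent oracle: explicit loop over positive/negative pairs."""
        for _ in range(20):
            scores = rng.integers(0, 6, size=24) / 5.0  # force ties
            labels = rng.integers(0, 2, size=24)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = pairs / (len(pos) * len(neg))
            assert compute_metrics(labels, scores)["auc"] == pytest.approx(expected)


class _ConstantModel:
    def predict_proba(self, X):
        return np.tile([0.6, 0.4], (len(X), 1))


class TestRepeatedCv:
    def test_folds_partition_each_repeat(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        seen = []

        def builder(Xtr, ytr, seed):
            seen.append(len(Xtr))
            return _ConstantModel()

        rep = repeated_cv(builder, X, y, folds=5, repeats=2, seed=0)
        assert len(rep.records) == 10
        # validation folds partition all 40 samples per repeat
        sizes = [len(s) for _, s in rep.fold_scores]
        assert sum(sizes[:5]) == 40 and sum(sizes[5:]) == 40

    def test_constant_classifier_auc_half(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.array([0, 1] * 15)
        rep = repeated_cv(lambda *a: _ConstantModel(), X, y, folds=5,
                          repeats=2, seed=1)
        assert all(r["auc"] == 0.5 for r in rep.records)

    def test_planted_signal_high_auc(self, rng):
        from sklearn.linear_model import LogisticRegression
        n = 200
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 5))
        X[:, 0] += 3.0 * y  # strong single-feature signal

        def builder(Xtr, ytr, seed):
            return LogisticRegression().fit(Xtr, ytr)

        rep = repeated_cv(builder, X, y, folds=5, repeats=2, seed=2)
        assert rep.mean("auc") > 0.9

    def test_unstratifiable_labels_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1] + [0] * 9)
        with pytest.raises(ValueError):
            repeated_cv(lambda *a: _ConstantModel(), X, y, folds=5, repeats=1)


class TestMeanRoc:
    def test_single_fold_equals_own_curve(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        grid, tpr = mean_roc_curve([(labels, scores)])
        from kpsfusion.evaluation import roc_curve_points
        fpr0, tpr0 = roc_curve_points(labels, scores)
        np.testing.assert_allclose(tpr[1:-1], np.interp(grid, fpr0, tpr0)[1:-1])

    def test_two_identical_folds_equal_either(self, rng):
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        scores = rng.random(25)
        _, one = mean_roc_curve([(labels, scores)])
        _, two = mean_roc_curve([(labels, scores), (labels, scores)])
        np.testing.assert_allclose(one, two)

    def test_monotone_nondecreasing(self, rng):
        folds = []
        for _ in range(6):
            labels = rng.integers(0, 2, 20)
            labels[:2] = [0, 1]
            folds.append((labels, rng.random(20)))
        _, tpr = mean_roc_curve(folds)
        assert (np.diff(tpr) >= -1e-12).all()
        assert tpr[0] == 0.0 and tpr[-1] == 1.0


class TestPairedT:
    def test_identical_series_flagged_tie(self):
        with pytest.warns(UserWarning):
            t, p = paired_t_test([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert np.isnan(t) and p == 1.0

    def test_constant_offset_degenerate(self):
        with pytest.warns(UserWarning):
            t, p = paired_t_test([0.7, 0.8, 0.9], [0.6, 0.7, 0.8])
        assert np.isnan(t)

    def test_hand_computed_t(self):
        a = np.array([0.7, 0.85, 0.9])
        b = np.array([0.6, 0.7, 0.8])
        t, p = paired_t_test(a, b)
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(expected)
        assert t == pytest.approx(7.0, abs=0.01)
        assert 0 < p < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2], [1, 2, 3])
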