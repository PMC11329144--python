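"""Metrics, AUC, folds, printed-table reconstruction, paired test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from bruitnet.evaluate import (
    ConfusionMatrix,
    auc_roc,
    compute_metrics,
    mcnemar_exact,
    reconstruct_confusion,
    stratified_folds,
)
from bruitnet.labeling import LabeledRecording
from bruitnet.synth import RecordingRecord
import datetime as dt


def _labeled(labels):
    day = dt.date(2021, 1, 1)
    return [
        LabeledRecording(
            RecordingRecord(f"P{i}", day + dt.timedelta(days=i), "arterial", None, "patent"),
            lab,
        )
        for i, lab in enumerate(labels)
    ]


class TestComputeMetrics:
    def test_published_scratch_row_counts(self):
        """(17, 6, 9, 79) reproduces the published train-from-scratch metrics."""
        m = compute_metrics(ConfusionMatrix(tp=17, fp=6, fn=9, tn=79))
        assert m.accuracy == pytest.approx(0.8649, abs=5e-5)
        assert m.precision == pytest.approx(0.7391, abs=5e-5)
        assert m.recall == pytest.approx(0.6538, abs=5e-5)
        assert m.f1 == pytest.approx(0.6939, abs=5e-5)

    def test_published_panns_row_counts(self):
        m = compute_metrics(ConfusionMatrix(tp=18, fp=4, fn=8, tn=81))
        assert m.accuracy == pytest.approx(0.8919, abs=5e-5)
        assert m.precision == pytest.approx(0.8182, abs=5e-5)
        assert m.recall == pytest.approx(0.6923, abs=5e-5)
        assert m.f1 == pytest.approx(0.7500, abs=5e-5)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=7))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominators_warn_and_give_nan(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            m = compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert np.isnan(m.precision)
        assert np.isnan(m.f1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)

    @given(
        tp=st.integers(0, 40), fp=st.integers(0, 40),
        fn=st.integers(0, 40), tn=st.integers(0, 40),
    )
    @settings(max_examples=80, deadline=None)
    def test_metric_bounds_and_f1_between_precision_recall(self, tp, fp, fn, tn):
        if tp + tn + fp + fn == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = compute_metrics(ConfusionMatrix(tp, fp, fn, tn))
        for v in (m.accuracy, m.precision, m.recall, m.f1):
            assert np.isnan(v) or 0.0 <= v <= 1.0
        if np.isfinite(m.f1):
            assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12


class TestAuc:
    def test_perfect_separation(self):
        assert auc_roc([(0.9, 1), (0.8, 1), (0.2, 0), (0.1, 0)]) == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        assert auc_roc([(0.5, 1), (0.5, 0), (0.5, 1), (0.5, 0)]) == pytest.approx(0.5)

    def test_three_of_four_pairs_ordered(self):
        scores = [(0.9, 1), (0.8, 0), (0.4, 1), (0.3, 0)]
        assert auc_roc(scores) == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_roc([(0.5, 1), (0.2, 1)])

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_pair_counting_and_reference(self, seed):
        """The trapezoidal ROC integral equals the Mann–Whitney pair statistic
        (exhaustive pair counting with ties at 1/2), and matches the
        scikit-learn reference implementation."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1
        s = np.round(rng.uniform(0, 1, size=40), 2)  # rounding forces ties
        scores = list(zip(s.tolist(), y.tolist()))
        pos = s[y == 1]
        neg = s[y == 0]
        pairs = (
            (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        ) / (len(pos) * len(neg))
        ours = auc_roc(scores)
        assert ours == pytest.approx(pairs, abs=1e-9)
        assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-9)


class TestStratifiedFolds:
    def test_cohort_sized_partition(self):
        """111 recordings with 26 abnormal: folds of 23/22/22/22/22 with
        6/5/5/5/5 abnormal."""
        labeled = _labeled(["abnormal"] * 26 + ["normal"] * 85)
        folds = stratified_folds(labeled, k=5, seed=0)
        sizes = sorted(np.bincount(folds), reverse=True)
        assert sizes == [23, 22, 22, 22, 22]
        pos_per_fold = sorted(
            (np.bincount(folds[np.arange(26)], minlength=5)), reverse=True
        )
        assert pos_per_fold == [6, 5, 5, 5, 5]

    def test_partition_covers_everything_once(self):
        labeled = _labeled(["abnormal"] * 10 + ["normal"] * 25)
        folds = stratified_folds(labeled, k=5, seed=3)
        assert folds.shape == (35,)
        assert set(folds) == set(range(5))

    def test_same_seed_same_assignment(self):
        labeled = _labeled(["abnormal"] * 10 + ["normal"] * 25)
        np.testing.assert_array_equal(
            stratified_folds(labeled, seed=4), stratified_folds(labeled, seed=4)
        )

    def test_too_few_per_class_raises(self):
        with pytest.raises(ValueError, match="each class"):
            stratified_folds(_labeled(["abnormal"] * 3 + ["normal"] * 20), k=5)

    def test_unlabeled_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            stratified_folds(_labeled(["unlabeled"] * 30))


class TestReconstructConfusion:
    def test_scratch_row_is_unique(self):
        out = reconstruct_confusion(0.8649, 0.7391, 0.6538, n_pos=26, n_neg=85)
        assert out == [ConfusionMatrix(tp=17, fp=6, fn=9, tn=79)]

    def test_human_evaluator_row_with_truncated_recall(self):
        """22/26 = 0.84615 truncates to the printed 0.8461."""
        out = reconstruct_confusion(0.7117, 0.4400, 0.8461, n_pos=26, n_neg=85)
        assert out == [ConfusionMatrix(tp=22, fp=28, fn=4, tn=57)]

    def test_perfect_row(self):
        out = reconstruct_confusion(1.0, 1.0, 1.0, n_pos=26, n_neg=85)
        assert out == [ConfusionMatrix(tp=26, fp=0, fn=0, tn=85)]

    def test_inconsistent_row_raises(self):
        with pytest.raises(ValueError, match="inconsistent"):
            reconstruct_confusion(0.9279, 0.8462, 0.8077, n_pos=26, n_neg=85)

    def test_bad_class_sizes_raise(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(0.9, 0.9, 0.9, n_pos=0, n_neg=85)


class TestMcNemar:
    def test_identical_predictions_give_p_one(self):
        correct = np.array([True, False, True, True])
        assert mcnemar_exact(correct, correct) == 1.0

    def test_one_sided_discordance_is_significant(self):
        a = np.ones(30, dtype=bool)
        b = np.zeros(30, dtype=bool)
        assert mcnemar_exact(a, b) < 1e-6

    def test_matches_binomial_closed_form(self):
        """Exact McNemar = two-sided binomial test on discordant pairs."""
        from scipy.stats import binomtest

        a = np.array([True] * 8 + [False] * 2 + [True] * 10)
        b = np.array([False] * 8 + [True] * 2 + [True] * 10)
        expected = binomtest(2, 10, 0.5).pvalue
        assert mcnemar_exact(a, b) == pytest.approx(expected, rel=1e-9)
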