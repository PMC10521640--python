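import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ramanres as rr
from ramanres.evaluate import evaluate_probabilities, run_baseline_classifiers
from ramanres.preprocess import PreprocessedMatrix, minmax


def mann_whitney_auc(y, s):
    """Exhaustive pair-enumeration oracle with half credit for ties."""
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


class TestConfusionCounts:
    def test_hand_tally(self):
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.6, 0.4, 0.3, 0.2, 0.1])
        assert rr.confusion_counts(y, p, 0.5) == (3, 1, 4, 2)

    def test_all_correct(self):
        y = np.array([1, 0])
        assert rr.confusion_counts(y, np.array([0.9, 0.1])) == (1, 0, 1, 0)

    def test_threshold_zero_predicts_everything_positive(self):
        y = np.array([1, 0, 1])
        tp, fp, tn, fn = rr.confusion_counts(y, np.array([0.1, 0.2, 0.3]), 0.0)
        assert tn == 0 and fn == 0 and tp == 2 and fp == 1

    def test_tie_at_threshold_counts_positive(self):
        assert rr.confusion_counts(np.array([1]), np.array([0.5]), 0.5) == (1, 0, 0, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rr.confusion_counts(np.array([]), np.array([]))


class TestComputeMetrics:
    def test_substitution_into_formulas(self):
        rep = rr.compute_metrics((3, 1, 4, 2))
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)
        assert rep.f1 == pytest.approx(6 / 9)

    def test_all_correct_gives_ones(self):
        rep = rr.compute_metrics((5, 0, 5, 0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (1, 1, 1, 1)

    def test_zero_denominator_reports_zero(self):
        rep = rr.compute_metrics((0, 0, 5, 5))
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.f1 == 0.0

    def test_brute_force_recomputation_on_random_counts(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fp + tn + fn == 0:
                continue
            rep = rr.compute_metrics((tp, fp, tn, fn))
            total = tp + fp + tn + fn
            assert rep.accuracy == (tp + tn) / total
            assert rep.precision == (tp / (tp + fp) if tp + fp else 0.0)
            assert rep.recall == (tp / (tp + fn) if tp + fn else 0.0)
            assert rep.f1 == (
                2 * tp / (2 * tp + fn + fp) if 2 * tp + fn + fp else 0.0
            )


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        curve, auc = rr.roc_auc(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc == 1.0

    def test_constant_scores_chance_line(self):
        y = np.array([0, 1, 0, 1])
        curve, auc = rr.roc_auc(y, np.full(4, 0.5))
        assert auc == 0.5
        np.testing.assert_array_equal(curve.tpr, [0.0, 1.0])
        np.testing.assert_array_equal(curve.fpr, [0.0, 1.0])

    def test_curve_monotone_with_unit_endpoints(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        curve, _ = rr.roc_auc(y, rng.random(40).round(1))
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert (curve.tpr[0], curve.fpr[0]) == (0.0, 0.0)
        assert (curve.tpr[-1], curve.fpr[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            rr.roc_auc(np.ones(4), np.random.rand(4))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 50))
    def test_matches_pair_enumeration_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        # coarse scores force ties
        s = rng.integers(0, 5, n) / 4.0
        _, auc = rr.roc_auc(y, s)
        assert auc == pytest.approx(mann_whitney_auc(y, s), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            y = rng.integers(0, 2, 30)
            y[:2] = [0, 1]
            s = rng.random(30).round(2)
            _, auc = rr.roc_auc(y, s)
            assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        _, a1 = rr.roc_auc(y, s)
        _, a2 = rr.roc_auc(y, np.exp(3 * s))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_invariant_to_sample_order(self, rng):
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        s = rng.random(25).round(1)
        perm = rng.permutation(25)
        _, a1 = rr.roc_auc(y, s)
        _, a2 = rr.roc_auc(y[perm], s[perm])
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestEvaluateModel:
    def test_oracle_predictor_scores_perfectly(self, small_matrix):
        truth = small_matrix.labels.astype(float)

        def oracle(values):
            return truth

        rep = rr.evaluate_model(oracle, small_matrix)
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_constant_predictor_boundary_semantics(self, small_matrix):
        rep = rr.evaluate_model(lambda v: np.full(v.shape[0], 0.5), small_matrix)
        assert rep.accuracy == 0.5  # ties predicted positive; balanced data
        assert rep.auc == 0.5

    def test_report_reproducible_from_counts(self, small_matrix, rng):
        rep = rr.evaluate_model(lambda v: rng.random(v.shape[0]), small_matrix)
        again = rr.compute_metrics((rep.tp, rep.fp, rep.tn, rep.fn))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (
            again.accuracy, again.precision, again.recall, again.f1,
        )
        assert rep.total == small_matrix.n

    def test_confusion_matrix_layout(self):
        rep = rr.compute_metrics((3, 1, 4, 2))
        np.testing.assert_array_equal(rep.confusion_matrix(), [[4, 1], [2, 3]])


def separable_matrix(n=150, n_channels=40, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.tile([0, 1], n // 2)
    base = rng.random((n, n_channels))
    base[:, 7] += 2.0 * labels  # one cleanly informative channel
    return PreprocessedMatrix(
        values=minmax(base),
        grid=np.linspace(385, 1545, n_channels),
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels,
    )


class TestBaselineHarness:
    @pytest.fixture(scope="class")
    def reports(self):
        m = separable_matrix()
        idx = np.arange(m.n)
        split = (idx[:100], idx[100:125], idx[125:])
        return run_baseline_classifiers(m, split, seed=0)

    def test_all_baselines_learn_separable_task(self, reports):
        assert set(reports) == {"svm", "random_forest", "xgboost", "lightgbm"}
        for name, parts in reports.items():
            assert parts["test"].accuracy >= 0.95, name

    def test_schema_identical_across_methods(self, reports):
        keys = [tuple(sorted(p["test"].to_dict())) for p in reports.values()]
        assert len(set(keys)) == 1

    def test_fixed_seed_reproducible(self):
        m = separable_matrix()
        idx = np.arange(m.n)
        split = (idx[:100], idx[100:125], idx[125:])
        a = run_baseline_classifiers(m, split, baseline_set=["random_forest"], seed=3)
        b = run_baseline_classifiers(m, split, baseline_set=["random_forest"], seed=3)
        assert a["random_forest"]["test"].to_dict() == b["random_forest"]["test"].to_dict()
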