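import numpy as np
import pytest

import ramanres as rr
from ramanres.preprocess import PreprocessedMatrix, minmax
from ramanres.train import (
    EnsembleConfig,
    EnsembleModel,
    TrainConfig,
    class_weights_inverse_frequency,
    split_indices,
)


def labelled_matrix(n=1000, n_channels=64, seed=0, patients=10):
    rng = np.random.default_rng(seed)
    labels = np.tile([0, 1], n // 2)
    values = minmax(rng.random((n, n_channels)) + 0.5 * labels[:, None])
    return PreprocessedMatrix(
        values=values,
        grid=np.linspace(385, 1545, n_channels),
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels,
        patient_ids=[f"P{i % patients}" for i in range(n)],
    )


class TestSplit:
    def test_fractions_and_stratification(self):
        m = labelled_matrix(1000)
        tr, va, te = rr.split_dataset(m, TrainConfig(seed=1))
        assert (tr.n, va.n, te.n) == (800, 100, 100)
        for part in (tr, va, te):
            assert part.labels.mean() == 0.5  # balanced input stays balanced
        ids = set(tr.sample_ids) | set(va.sample_ids) | set(te.sample_ids)
        assert len(ids) == 1000  # disjoint and exhaustive

    def test_same_seed_identical_partitions(self):
        m = labelled_matrix(200)
        a = split_indices(m.labels, TrainConfig(seed=5), m.patient_ids)
        b = split_indices(m.labels, TrainConfig(seed=5), m.patient_ids)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_patient_mode_keeps_patients_whole(self):
        m = labelled_matrix(300, patients=15)
        cfg = TrainConfig(split_mode="patient", seed=2)
        tr, va, te = rr.split_dataset(m, cfg)
        groups = [set(p.patient_ids) for p in (tr, va, te)]
        assert groups[0] & groups[1] == set()
        assert groups[0] & groups[2] == set()
        assert groups[1] & groups[2] == set()

    def test_patient_mode_without_ids_rejected(self):
        with pytest.raises(ValueError, match="patient"):
            split_indices(np.tile([0, 1], 50), TrainConfig(split_mode="patient"))


class TestWeightedLoss:
    def test_perfect_predictions_near_zero(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([1.0, 0.0, 1.0, 0.0])
        assert rr.weighted_loss(y, p) < 1e-5

    def test_uninformative_prediction_is_ln2(self):
        y = np.array([1, 0, 1, 0])
        assert rr.weighted_loss(y, np.full(4, 0.5)) == pytest.approx(np.log(2))

    def test_inverse_frequency_weighting_by_substitution(self):
        # 25 positives, 75 negatives: w1 = 100/50 = 2, so a single positive
        # at p = 0.5 costs 2 ln 2
        y_cohort = np.array([1] * 25 + [0] * 75)
        weights = class_weights_inverse_frequency(y_cohort)
        assert weights == (100 / 150, 2.0)
        loss = rr.weighted_loss(np.array([1.0]), np.array([0.5]), weights)
        assert loss == pytest.approx(2 * np.log(2))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rr.weighted_loss(np.array([1, 0]), np.array([0.5]))

    def test_extreme_probabilities_clamped(self):
        val = rr.weighted_loss(np.array([1.0]), np.array([0.0]))
        assert np.isfinite(val)


class TestTrainLoop:
    def test_zero_epochs_leaves_model_untouched(self, tiny_model_cfg):
        m = labelled_matrix(64, n_channels=tiny_model_cfg.input_length)
        model = rr.build_model(tiny_model_cfg)
        before = model.copy_state()
        cfg = TrainConfig(epochs=0, batch_size=16)
        rr.train(model, m, m, cfg)
        for k, v in model.state_arrays().items():
            np.testing.assert_array_equal(v, before[k])
        assert model.history["train_loss"] == []

    def test_history_bookkeeping_and_determinism(self, tiny_model_cfg):
        m = labelled_matrix(80, n_channels=tiny_model_cfg.input_length, seed=3)
        cfg = TrainConfig(epochs=3, batch_size=16, learning_rate=1e-3, seed=4)
        runs = []
        for _ in range(2):
            model = rr.build_model(tiny_model_cfg)
            rr.train(model, m, m, cfg)
            runs.append(model.history)
        hist = runs[0]
        for key in ("train_loss", "train_acc", "val_loss", "val_acc"):
            assert len(hist[key]) == 3
            assert hist[key] == runs[1][key]

    def test_loss_decreases_on_learnable_task(self, tiny_model_cfg):
        m = labelled_matrix(128, n_channels=tiny_model_cfg.input_length, seed=5)
        model = rr.build_model(tiny_model_cfg)
        cfg = TrainConfig(epochs=8, batch_size=32, learning_rate=1e-3, seed=6,
                          selection="last")
        rr.train(model, m, m, cfg)
        losses = model.history["train_loss"]
        assert np.mean(losses[-2:]) < np.mean(losses[:2])

    def test_empty_training_set_rejected(self, tiny_model_cfg):
        m = labelled_matrix(16, n_channels=tiny_model_cfg.input_length)
        empty = m.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty|labels"):
            rr.train(rr.build_model(tiny_model_cfg), empty, m, TrainConfig(epochs=1))


class TestStrategyInputs:
    def test_original_is_identity(self, small_matrix):
        (out,) = rr.make_strategy_inputs(small_matrix, "original")
        assert out is small_matrix

    def test_split_windows_cover_low_shift_channels(self, small_matrix):
        a, b = rr.make_strategy_inputs(small_matrix, "split")
        assert a.values.shape[1] == 512 and b.values.shape[1] == 512
        np.testing.assert_array_equal(a.grid, small_matrix.grid[0:512])
        np.testing.assert_array_equal(b.grid, small_matrix.grid[128:640])
        # each window row is renormalized
        np.testing.assert_array_equal(a.values.max(axis=1), 1.0)

    def test_intensify_factor_one_is_renormalized_original(self, small_matrix):
        from ramanres.augment import IntensifyConfig

        (out,) = rr.make_strategy_inputs(
            small_matrix, "intensify", IntensifyConfig(factor=1.0)
        )
        np.testing.assert_allclose(out.values, minmax(small_matrix.values), atol=1e-12)

    def test_unknown_strategy_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="strategy"):
            rr.make_strategy_inputs(small_matrix, "bogus")


class _Stub:
    def __init__(self, value):
        self.value = value

    def predict_proba(self, values):
        return np.full(values.shape[0], self.value)


def stub_ensemble(p_orig, p_int, p_s0, p_s1, weights=(8.0, 1.0, 1.0)):
    return EnsembleModel(
        original=_Stub(p_orig),
        intensify=_Stub(p_int),
        split=[_Stub(p_s0), _Stub(p_s1)],
        config=EnsembleConfig(weights=weights),
    )


class TestEnsembleArithmetic:
    def test_default_weights_normalize(self):
        assert EnsembleConfig().normalized_weights() == (0.8, 0.1, 0.1)

    def test_weighted_average(self, small_matrix):
        ens = stub_ensemble(0.9, 0.5, 0.2, 0.0)
        p = rr.ensemble_predict(ens, small_matrix)
        np.testing.assert_allclose(p, 0.8 * 0.9 + 0.1 * 0.5 + 0.1 * 0.1)

    def test_identical_members_reproduce_their_value(self, small_matrix):
        p = rr.ensemble_predict(stub_ensemble(0.3, 0.3, 0.3, 0.3), small_matrix)
        np.testing.assert_allclose(p, 0.3)

    def test_convex_combination_bounds(self, small_matrix):
        ens = stub_ensemble(1.0, 0.0, 0.0, 0.0)
        p = rr.ensemble_predict(ens, small_matrix)
        assert np.all(p >= 0.0) and np.all(p <= 1.0)
        np.testing.assert_allclose(p, 0.8)

    def test_missing_member_rejected(self, small_matrix):
        ens = stub_ensemble(0.5, 0.5, 0.5, 0.5)
        ens.split = []
        with pytest.raises(ValueError, match="member"):
            rr.ensemble_predict(ens, small_matrix)
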