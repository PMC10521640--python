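import numpy as np
import pytest

import ramanres as rr
from ramanres.nn.layers import BatchNorm1d, Conv1d, ReLU, sigmoid
from ramanres.resnet import BlockSpec, ModelConfig, _ResidualBlock, load_model


class TestActivations:
    def test_sigmoid_at_zero_is_half(self):
        assert sigmoid(np.array([0.0]))[0] == 0.5

    def test_relu_on_mixed_signs(self):
        relu = ReLU()
        out = relu.forward(np.array([[-1.0, 2.0, 0.0, -3.5]]))
        np.testing.assert_array_equal(out, [[0.0, 2.0, 0.0, 0.0]])


class TestBatchNorm:
    def test_training_mode_standardizes(self, rng):
        bn = BatchNorm1d(4, dtype=np.float64)
        x = rng.random((8, 4, 16)) * 3 + 1
        out = bn.forward(x, training=True)
        np.testing.assert_allclose(out.mean(axis=(0, 2)), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=(0, 2)), 1.0, atol=1e-4)

    def test_zero_gamma_gives_constant_beta(self, rng):
        bn = BatchNorm1d(3, dtype=np.float64)
        bn.params["gamma"][:] = 0.0
        bn.params["beta"][:] = 2.5
        out = bn.forward(rng.random((4, 3, 8)), training=True)
        np.testing.assert_array_equal(out, np.full((4, 3, 8), 2.5))

    def test_matches_two_pass_oracle(self, rng):
        # hand-rolled per-channel mean/variance standardization
        bn = BatchNorm1d(4, dtype=np.float64)
        x = rng.random((8, 4, 1))
        out = bn.forward(x, training=True)
        expected = np.empty_like(x)
        for c in range(4):
            vals = x[:, c, :]
            mu = vals.sum() / vals.size
            var = ((vals - mu) ** 2).sum() / vals.size
            expected[:, c, :] = (vals - mu) / np.sqrt(var + bn.eps)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_batch_of_one_rejected_in_training(self):
        with pytest.raises(ValueError, match="batch size"):
            BatchNorm1d(2).forward(np.ones((1, 2, 4)), training=True)


class TestArchitecture:
    def test_default_pre_head_feature_map_shape(self):
        model = rr.build_model(ModelConfig())
        assert model.pre_head_shape(4) == (4, 1024, 1)
        x = np.random.default_rng(0).random((4, 1, 1024))
        model.forward_logits(x, capture=True)
        assert model.block_outputs[-1].shape == (4, 1024, 1)

    def test_probabilities_strictly_inside_unit_interval(self):
        model = rr.build_model(ModelConfig.compact())
        p = model.predict_proba(np.random.default_rng(1).random((3, 1024)))
        assert np.all(p > 0.0) and np.all(p < 1.0)

    def test_zeroed_normal_block_is_identity(self, rng):
        spec = BlockSpec("normal", 8, 8, 32)
        block = _ResidualBlock(spec, 3, 0.0, np.random.default_rng(0), np.float64)
        for conv in (block.conv1, block.conv2):
            conv.params["w"][:] = 0.0
            conv.params["b"][:] = 0.0
        x = rng.random((2, 8, 32))
        np.testing.assert_array_equal(block.forward(x), x)

    def test_downsample_block_halves_length(self, rng):
        spec = BlockSpec("downsample", 8, 16, 32)
        block = _ResidualBlock(spec, 3, 0.0, np.random.default_rng(0), np.float64)
        out = block.forward(rng.random((2, 8, 32)))
        assert out.shape == (2, 16, 16)

    def test_stagewise_length_halving(self, tiny_model_cfg):
        model = rr.build_model(tiny_model_cfg)
        lengths = [s.out_length for s in model.block_specs[1::2]]
        assert lengths == [
            tiny_model_cfg.input_length // 2**k
            for k in range(1, tiny_model_cfg.n_stages + 1)
        ]

    def test_parameter_count_is_config_determined(self):
        # regression constant for the default topology
        assert rr.build_model(ModelConfig()).n_parameters == 77_323_841
        # and is independent of the initialization seed
        assert rr.build_model(ModelConfig(seed=99)).n_parameters == 77_323_841

    def test_channel_schedule_defaults_double_to_cap(self):
        cfg = ModelConfig()
        assert cfg.resolved_schedule() == [64, 128, 256, 512, 1024] + [1024] * 5

    def test_shrinking_schedule_rejected(self):
        cfg = ModelConfig(
            input_length=64, stem_channels=8, n_stages=2, channel_schedule=[16, 8]
        )
        with pytest.raises(ValueError, match="shrink"):
            rr.build_model(cfg)

    def test_indivisible_input_length_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_length=1000, n_stages=10).validate()

    def test_scaled_config_for_half_grid(self):
        half = ModelConfig().scaled_to(512)
        assert half.n_stages == 9 and half.input_length == 512
        half.validate()


class TestForward:
    def test_duplicate_rows_get_identical_probabilities(self, tiny_model_cfg, rng):
        model = rr.build_model(tiny_model_cfg)
        row = rng.random(tiny_model_cfg.input_length)
        p = model.predict_proba(np.stack([row, row]))
        assert p[0] == p[1]

    def test_wrong_length_raises_shape_error(self, tiny_model_cfg):
        model = rr.build_model(tiny_model_cfg)
        with pytest.raises(ValueError, match=str(tiny_model_cfg.input_length)):
            model.forward_logits(np.ones((2, 1, 100)))

    def test_gradient_reaches_stem(self, tiny_model_cfg, rng):
        model = rr.build_model(tiny_model_cfg)
        x = rng.random((4, tiny_model_cfg.input_length))
        model.forward_logits(x, training=True, rng=rng)
        model.backward(np.ones(4))
        assert np.linalg.norm(model.stem.grads["w"]) > 0

    def test_seeded_init_is_reproducible(self, tiny_model_cfg, rng):
        a = rr.build_model(tiny_model_cfg)
        b = rr.build_model(tiny_model_cfg)
        x = rng.random((2, tiny_model_cfg.input_length))
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))


class TestBackward:
    def test_analytic_gradients_match_finite_differences(self):
        # full-network check in float64, exact loss recomputation oracle
        cfg = ModelConfig(
            input_length=32, stem_channels=4, n_stages=2, channel_cap=8,
            dropout_rate=0.0, seed=7, dtype="float64",
        )
        model = rr.build_model(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((6, 32))
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 1.0])

        def loss():
            logits = model.forward_logits(x, training=True)
            p = sigmoid(logits)
            return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)), logits

        _, logits = loss()
        p = sigmoid(logits)
        model.backward((p - y) / y.size)
        check_rng = np.random.default_rng(1)
        for mod in model.modules():
            for name, par in mod.params.items():
                g = mod.grads.get(name)
                if g is None:
                    continue
                flat, gflat = par.reshape(-1), g.reshape(-1)
                for k in check_rng.integers(0, flat.size, size=2):
                    eps, old = 1e-6, flat[k]
                    flat[k] = old + eps
                    up, _ = loss()
                    flat[k] = old - eps
                    down, _ = loss()
                    flat[k] = old
                    num = (up - down) / (2 * eps)
                    assert abs(num - gflat[k]) < 1e-7

    def test_conv_backward_input_gradient(self, rng):
        # finite differences on the input, stride 2 with projection-style 1x1
        for stride, k, pad in ((1, 3, 1), (2, 3, 1), (2, 1, 0)):
            conv = Conv1d(2, 3, k, stride, pad, rng=np.random.default_rng(0),
                          dtype=np.float64)
            x = rng.random((2, 2, 8))
            out = conv.forward(x, training=True)
            dout = rng.random(out.shape)
            dx = conv.backward(dout)
            for idx in [(0, 0, 0), (1, 1, 3), (0, 1, 7)]:
                eps = 1e-6
                xp = x.copy(); xp[idx] += eps
                xm = x.copy(); xm[idx] -= eps
                num = (
                    (conv.forward(xp) * dout).sum() - (conv.forward(xm) * dout).sum()
                ) / (2 * eps)
                assert abs(num - dx[idx]) < 1e-6


class TestPersistence:
    def test_save_load_round_trip(self, tiny_model_cfg, tmp_path, rng):
        model = rr.build_model(tiny_model_cfg)
        model.history = {"train_loss": [0.5, 0.4]}
        x = rng.random((3, tiny_model_cfg.input_length))
        before = model.predict_proba(x)
        path = tmp_path / "model.rnn"
        model.save(path)
        back = load_model(path)
        np.testing.assert_array_equal(back.predict_proba(x), before)
        assert back.history == model.history
        assert back.config.n_stages == tiny_model_cfg.n_stages

    def test_describe_lists_every_block(self, tiny_model_cfg):
        model = rr.build_model(tiny_model_cfg)
        text = model.describe()
        assert text.count("normal") == tiny_model_cfg.n_stages
        assert text.count("downsample") == tiny_model_cfg.n_stages
        assert "sigmoid" in text
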