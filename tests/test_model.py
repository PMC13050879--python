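"""Decoder assembly: shapes, recalibration, loss, parameter accounting."""

import numpy as np
import pytest

from apcformer.model import (
    AFR,
    APCformer,
    CBAM,
    ModelConfig,
    count_parameters,
    cross_entropy_loss,
    load_checkpoint,
    save_checkpoint,
)
from apcformer.nn import Tensor
from apcformer.sat import SATConfig


def dataset1_config(**overrides) -> ModelConfig:
    return ModelConfig(**overrides)


def dataset2_config() -> ModelConfig:
    return ModelConfig(C=3, n_classes=2,
                       sat=SATConfig(n_layers=4, window=5))


class TestShapeChain:
    def test_reference_shapes_end_to_end(self):
        cfg = dataset1_config(dropout=0.0)
        cfg.sat.dropout = 0.0
        model = APCformer(cfg, seed=0).eval()
        x = np.random.default_rng(0).standard_normal((2, 1, 22, 1000)).astype(
            np.float32)
        branches = model.stconv(Tensor(x))
        for b in branches:
            assert b.shape == (2, 32, 1, 13)
        recal = model.afr(branches)
        from apcformer.nn import concatenate

        fused = concatenate(recal, axis=3)
        assert fused.shape == (2, 32, 1, 39)
        tokens = model.pae(fused)
        assert tokens.shape == (2, 13, 32)
        probs = model(x)
        assert probs.shape == (2, 4)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_temporal_kernels_are_odd_fractions_of_fs(self):
        cfg = dataset1_config()
        assert cfg.temporal_kernels == (125, 63, 31)

    def test_batch_output_shape(self):
        model = APCformer(dataset2_config(), seed=0).eval()
        x = np.zeros((32, 1, 3, 1000), np.float32)
        assert model(x).shape == (32, 2)

    def test_wrong_input_shape_rejected(self):
        model = APCformer(dataset2_config(), seed=0)
        with pytest.raises(ValueError, match="expected input"):
            model(np.zeros((2, 1, 5, 1000), np.float32))


class TestCBAM:
    def test_shape_preserved_and_weights_bounded(self):
        rng = np.random.default_rng(0)
        cbam = CBAM(8, reduction=4, rng=rng)
        x = Tensor(rng.standard_normal((3, 8, 1, 10)).astype(np.float32))
        out = cbam(x)
        assert out.shape == x.shape
        # multiplicative gates in (0,1): |out| strictly below |in| wherever
        # the input is nonzero
        assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-7)
        nz = np.abs(x.data) > 1e-3
        assert np.all(np.abs(out.data[nz]) < np.abs(x.data[nz]))

    def test_zero_input_with_zero_bias_gives_half_gates(self):
        rng = np.random.default_rng(1)
        cbam = CBAM(8, reduction=4, rng=rng)
        for p in cbam.parameters():
            p.data = np.zeros_like(p.data)  # weights and biases zero
        x = Tensor(np.zeros((2, 8, 1, 6), np.float32))
        gate = (cbam._mlp(x.reshape(2, 8, -1).max(axis=2))
                + cbam._mlp(x.reshape(2, 8, -1).mean(axis=2))).sigmoid()
        np.testing.assert_allclose(gate.data, 0.5)  # sigmoid(0)
        np.testing.assert_allclose(cbam(x).data, 0.0)


class TestAFR:
    def test_interaction_is_cross_branch_sum(self):
        rng = np.random.default_rng(2)
        x = Tensor(rng.standard_normal((2, 4, 1, 5)))
        zero = Tensor(np.zeros((2, 4, 1, 5)))
        mixed = AFR.interact([x, zero, zero])
        for out in mixed:
            np.testing.assert_array_equal(out.data, x.data)
        a, b, c = (Tensor(rng.standard_normal((2, 4, 1, 5)))
                   for _ in range(3))
        total = a.data + b.data + c.data
        for out in AFR.interact([a, b, c]):
            np.testing.assert_allclose(out.data, total, atol=1e-12)

    def test_branch_cbams_have_independent_parameters(self, tiny_model_config):
        rng = np.random.default_rng(3)
        afr = AFR(tiny_model_config, rng)
        x = Tensor(rng.standard_normal((2, 8, 1, 6)).astype(np.float32))
        outs = afr([x, x, x])
        # same input into each branch, but differently initialized CBAMs
        assert not np.allclose(outs[0].data, outs[1].data)
        assert not np.allclose(outs[1].data, outs[2].data)


class TestPAE:
    def test_zero_positional_matrix_is_additive_identity(self,
                                                         tiny_model_config):
        from apcformer.model import PAE

        rng = np.random.default_rng(4)
        pae = PAE(tiny_model_config, rng)
        pae.eval()
        fused = Tensor(rng.standard_normal((2, 8, 1, 24)).astype(np.float32))
        with_pos = pae(fused)
        positional = pae.positional.data.copy()
        pae.positional.data = np.zeros_like(positional)
        without_pos = pae(fused)
        assert with_pos.shape == (2, 8, 8)
        # the encoding is purely additive: the difference per batch item is
        # exactly the positional matrix, and zeroing it is the identity
        np.testing.assert_allclose(
            with_pos.data - without_pos.data,
            np.broadcast_to(positional, with_pos.shape), atol=1e-6)

    def test_same_seed_same_positional_init(self, tiny_model_config):
        m1 = APCformer(tiny_model_config, seed=7)
        m2 = APCformer(tiny_model_config, seed=7)
        np.testing.assert_array_equal(m1.pae.positional.data,
                                      m2.pae.positional.data)
        m3 = APCformer(tiny_model_config, seed=8)
        assert not np.array_equal(m1.pae.positional.data,
                                  m3.pae.positional.data)

    def test_positional_matrix_receives_gradient(self, tiny_model_config):
        model = APCformer(tiny_model_config, seed=0)
        model.eval()  # disable dropout; gradients still flow
        x = np.random.default_rng(1).standard_normal((4, 1, 3, 200)).astype(
            np.float32)
        probs = model(x)
        loss = cross_entropy_loss(probs, np.array([0, 1, 0, 1]))
        model.zero_grad()
        loss.backward()
        grad = model.pae.positional.grad
        assert grad is not None
        assert np.abs(grad).max() > 0


class TestClassifierAndLoss:
    def test_probabilities_sum_to_one(self, tiny_model_config):
        model = APCformer(tiny_model_config, seed=0).eval()
        x = np.random.default_rng(2).standard_normal((5, 1, 3, 200)).astype(
            np.float32)
        np.testing.assert_allclose(model(x).data.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_prediction_loss_is_log_n_classes(self):
        probs = Tensor(np.full((6, 4), 0.25))
        loss = cross_entropy_loss(probs, np.array([0, 1, 2, 3, 0, 1]))
        assert float(loss.data) == pytest.approx(np.log(4), abs=1e-9)

    def test_perfect_prediction_loss_is_zero(self):
        probs = Tensor(np.eye(3)[np.array([0, 2, 1])])
        loss = cross_entropy_loss(probs, np.array([0, 2, 1]))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_sample_loop_oracle(self):
        rng = np.random.default_rng(5)
        logits = rng.standard_normal((7, 4))
        probs_np = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        labels = rng.integers(0, 4, 7)
        loss = cross_entropy_loss(Tensor(probs_np), labels)
        oracle = -np.mean([np.log(probs_np[i, labels[i]])
                           for i in range(7)])
        assert float(loss.data) == pytest.approx(oracle, abs=1e-12)

    def test_zero_probability_guarded(self):
        probs = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        loss = cross_entropy_loss(probs, np.array([1, 0]))
        assert np.isfinite(loss.data)


class TestParameterCount:
    def test_dataset1_count_near_printed_scale(self):
        model = APCformer(dataset1_config(), seed=0)
        total, breakdown = count_parameters(model)
        assert 40_000 < total < 50_000  # ~45.5K scale
        assert set(breakdown) == {"branches", "afr", "pae", "sat", "head"}
        assert sum(breakdown.values()) == total

    def test_doubling_f2_strictly_increases_count(self):
        small = ModelConfig(F2=32, sat=SATConfig(d_model=32))
        big = ModelConfig(F2=64, sat=SATConfig(d_model=64))
        assert (count_parameters(APCformer(big, 0))[0]
                > count_parameters(APCformer(small, 0))[0])

    def test_channel_count_touches_only_spatial_convs(self):
        t22, b22 = count_parameters(APCformer(dataset1_config(), 0))
        t10, b10 = count_parameters(APCformer(dataset1_config(C=10), 0))
        assert b22["afr"] == b10["afr"]
        assert b22["pae"] == b10["pae"]
        assert b22["sat"] == b10["sat"]
        assert b22["head"] == b10["head"]
        assert b22["branches"] > b10["branches"]

    def test_class_count_touches_only_head(self):
        t4, b4 = count_parameters(APCformer(dataset1_config(), 0))
        t2, b2 = count_parameters(APCformer(dataset1_config(n_classes=2), 0))
        assert b4["head"] > b2["head"]
        for key in ("branches", "afr", "pae", "sat"):
            assert b4[key] == b2[key]

    def test_count_is_batch_independent(self, tiny_model_config):
        model = APCformer(tiny_model_config, seed=0).eval()
        before = count_parameters(model)[0]
        model(np.zeros((3, 1, 3, 200), np.float32))
        model(np.zeros((9, 1, 3, 200), np.float32))
        assert count_parameters(model)[0] == before


class TestDeterminism:
    def test_eval_forward_is_pure(self, tiny_model_config):
        model = APCformer(tiny_model_config, seed=0).eval()
        x = np.random.default_rng(3).standard_normal((4, 1, 3, 200)).astype(
            np.float32)
        np.testing.assert_array_equal(model(x).data, model(x).data)

    def test_checkpoint_round_trip(self, tiny_model_config, tmp_path):
        model = APCformer(tiny_model_config, seed=0).eval()
        x = np.random.default_rng(4).standard_normal((3, 1, 3, 200)).astype(
            np.float32)
        ref = model(x).data
        path = save_checkpoint(model, tmp_path / "model.npz")
        loaded = load_checkpoint(path)
        np.testing.assert_array_equal(loaded(x).data, ref)
        assert loaded.cfg.C == model.cfg.C


class TestConfigSwitches:
    def test_standard_spatial_conv_dominates_count(self):
        dw = count_parameters(
            APCformer(dataset1_config(spatial_conv_mode="depthwise"), 0))[0]
        std = count_parameters(
            APCformer(dataset1_config(spatial_conv_mode="standard"), 0))[0]
        assert std > dw + 25_000  # C*F1*F2 per branch vs C*F2

    def test_hidden_classifier_layer_available(self):
        single = count_parameters(
            APCformer(dataset1_config(classifier_hidden=None), 0))[0]
        hidden = count_parameters(
            APCformer(dataset1_config(classifier_hidden=32), 0))[0]
        assert hidden > single

    def test_sat_ffn_sublayer_available(self):
        cfg = dataset1_config()
        cfg.sat.ffn_expansion = 1.0
        with_ffn = count_parameters(APCformer(cfg, 0))[0]
        without = count_parameters(APCformer(dataset1_config(), 0))[0]
        assert with_ffn > without
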