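"""Architecture construction, forward semantics, and parameter accounting."""

import numpy as np
import pytest

from portnet import nn
from portnet.config import (ArchitectureConfig, BlockSpec, ConfigurationError,
                            portnet_reference, toy_config)
from portnet.model import (build_model, count_params_closed_form,
                           introspect_params, load_checkpoint, save_checkpoint,
                           se_gate)


def softmax_rows(logits):
    return nn.softmax(logits)


class TestConfigValidation:
    def test_reference_table_is_valid(self):
        cfg = portnet_reference()
        assert len(cfg.blocks) == 13
        assert cfg.total_stride == 32

    def test_channel_chain_mismatch_names_block(self):
        cfg = portnet_reference()
        bad = ArchitectureConfig(
            blocks=[cfg.blocks[0],
                    BlockSpec("proj_block", 24, 48, 2, 6),
                    BlockSpec("proj_block", 99, 96, 2, 12),  # broken chain
                    BlockSpec("head", 96, 3)],
            num_classes=3, input_size=96)
        with pytest.raises(ConfigurationError, match="block 2"):
            bad.validate()

    def test_id_block_requires_equal_channels_and_stride_one(self):
        with pytest.raises(ConfigurationError):
            BlockSpec("id_block", 96, 192, 1, 6).validate(4)
        with pytest.raises(ConfigurationError):
            BlockSpec("id_block", 96, 96, 2, 6).validate(4)

    def test_input_size_must_match_stride_product(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            portnet_reference(input_size=100).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = portnet_reference(input_size=96)
        path = tmp_path / "arch.yaml"
        cfg.to_yaml(path)
        back = ArchitectureConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()


class TestForward:
    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(portnet_reference(input_size=224), seed=0)
        x = rng.random((2, 3, 224, 224), dtype=np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (2, 3)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_resolution_agnostic_down_to_total_stride(self, rng):
        model = build_model(portnet_reference(input_size=96), seed=0)
        out = model.forward(rng.random((1, 3, 96, 96), dtype=np.float32))
        assert out.shape == (1, 3)

    def test_deterministic_initialization(self, rng):
        a = build_model(toy_config(), seed=42)
        b = build_model(toy_config(), seed=42)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)
        x = rng.random((2, 3, 96, 96), dtype=np.float32)
        np.testing.assert_array_equal(a.forward(x), b.forward(x))

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_model(toy_config(), seed=1)
        x = rng.random((2, 3, 96, 96), dtype=np.float32)
        before = model.forward(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        np.testing.assert_array_equal(load_checkpoint(path).forward(x), before)


class TestParamCounting:
    def test_reference_total_and_blockwise_agreement(self):
        cfg = portnet_reference(num_classes=3)
        closed = count_params_closed_form(cfg)
        intro = introspect_params(build_model(cfg, seed=0))
        assert closed.per_block == intro.per_block
        assert closed.total == intro.total == 2_621_827

    @pytest.mark.parametrize("index,expected", [(0, 696), (3, 11_718), (12, 2_307)])
    def test_hand_computed_block_counts(self, index, expected):
        # stem(3->24)=27*24+2*24; id(C=96,h=6)=96^2+14*96+2*96*6+6; head=768*3+3
        closed = count_params_closed_form(portnet_reference())
        assert closed.per_block[index][1] == expected

    def test_count_independent_of_input_size(self):
        a = count_params_closed_form(portnet_reference(input_size=96))
        b = count_params_closed_form(portnet_reference(input_size=224))
        assert a.total == b.total

    def test_oracle_equivalence_on_random_configs(self):
        from conftest import random_valid_config
        rng = np.random.default_rng(7)
        for _ in range(10):
            cfg = random_valid_config(rng)
            closed = count_params_closed_form(cfg)
            intro = introspect_params(build_model(cfg, seed=0))
            assert closed.per_block == intro.per_block


class TestSEGate:
    def test_zero_weights_give_half_gates(self, rng):
        gate = nn.SEGate(8, 4, rng=np.random.default_rng(0))
        for p in gate.params():
            p.value[...] = 0.0
        x = rng.random((2, 8, 5, 5), dtype=np.float32)
        np.testing.assert_allclose(se_gate(x, gate), 0.5 * x, rtol=1e-6)

    def test_zero_input_stays_zero_and_gates_shrink(self, rng):
        gate = nn.SEGate(8, 4, rng=np.random.default_rng(1))
        zeros = np.zeros((1, 8, 4, 4), dtype=np.float32)
        np.testing.assert_array_equal(se_gate(zeros, gate), zeros)
        x = rng.standard_normal((2, 8, 4, 4)).astype(np.float32)
        out = se_gate(x, gate)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)

    def test_channel_mismatch_raises(self, rng):
        gate = nn.SEGate(8, 4)
        with pytest.raises(ValueError):
            se_gate(rng.random((1, 6, 4, 4), dtype=np.float32), gate)


class TestResidualAndGradients:
    def test_projection_block_residual_property(self, rng):
        """With main-path conv weights zeroed and BN at identity, a
        projection block reduces to SE(ReLU(skip(x)))."""
        from portnet.model import _ResidualBlock

        spec = BlockSpec("proj_block", 8, 16, 2, 4)
        block = _ResidualBlock(spec, np.random.default_rng(0))
        block.pw.weight.value[...] = 0.0
        for bn in (block.bn1, block.bn2):
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 1.0
            bn.eps = 0.0
        x = rng.random((2, 8, 8, 8), dtype=np.float32)
        out = block.forward(x, train=False)
        skip = block.skip_bn.forward(block.skip_conv.forward(x, train=False), train=False)
        expected = block.se.forward(np.maximum(skip, 0.0), train=False)
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_every_parameter_receives_gradient(self, rng):
        model = build_model(portnet_reference(input_size=96), seed=0)
        x = rng.random((2, 3, 96, 96), dtype=np.float32)
        logits = model.forward(x, train=True)
        _, dlogits = nn.cross_entropy(logits, np.array([0, 2]))
        model.zero_grad()
        model.backward(dlogits)
        for p in model.params():
            assert np.isfinite(p.grad).all()
            assert p.grad.shape == p.value.shape
        # gradient reaches the earliest layer
        assert np.abs(model.blocks[0].conv.weight.grad).max() > 0
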