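"""Backbone architecture contract, length invariance, checkpoints."""

import numpy as np
import pytest

from bruitnet.model import (
    CNN14,
    ModelConfig,
    load_checkpoint,
    load_external_checkpoint,
    save_checkpoint,
)


def conv_block_parameters(c_in, c_out):
    """Analytic parameter count of one block: two convs (+bias) and two BNs."""
    return (9 * c_in * c_out + c_out) + (9 * c_out * c_out + c_out) + 4 * c_out


@pytest.fixture(scope="module")
def full_width_model():
    """The ~80M-parameter full backbone; built once for this module."""
    return CNN14(ModelConfig(projection_head=False), seed=0)


class TestArchitecture:
    def test_full_width_layer_table(self, full_width_model):
        """At width_scale 1 the layer sequence and channel counts match the
        published backbone row for row."""
        model = full_width_model
        assert model.architecture_summary() == [
            "conv3x3 @ 64 (BN, ReLU) x 2",
            "maxpool 2x2",
            "conv3x3 @ 128 (BN, ReLU) x 2",
            "maxpool 2x2",
            "conv3x3 @ 256 (BN, ReLU) x 2",
            "maxpool 2x2",
            "conv3x3 @ 512 (BN, ReLU) x 2",
            "maxpool 2x2",
            "conv3x3 @ 1024 (BN, ReLU) x 2",
            "maxpool 2x2",
            "conv3x3 @ 2048 (BN, ReLU) x 2",
            "maxpool 2x2",
            "global pooling",
            "fc 2048 (ReLU)",
            "fc 2 (sigmoid)",
        ]

    def test_embedding_dimension_is_2048_at_full_width(self, full_width_model):
        full_width_model.eval()
        spec = np.zeros((1, 64, 64), dtype=np.float32)
        assert full_width_model.embed(spec).shape == (1, 2048)

    def test_width_scale_reduces_conv_parameters_quadratically(self, full_width_model):
        """Desk profile: conv-block parameters shrink by ~width_scale^2,
        verified against analytic per-layer counts."""
        def block_params(model):
            return sum(
                p.data.size
                for name, p in model.named_parameters().items()
                if name.startswith("blocks.")
            )

        for ws, model in ((1, full_width_model), (8, CNN14(ModelConfig(width_scale=8), seed=0))):
            chans = ModelConfig(width_scale=ws).scaled_channels
            expected = sum(
                conv_block_parameters(ci, co)
                for ci, co in zip((1,) + chans[:-1], chans)
            )
            assert block_params(model) == expected
        full = ModelConfig(width_scale=1).scaled_channels
        desk = ModelConfig(width_scale=8).scaled_channels
        # dominant (block-6) term scales exactly as ws^2
        assert full[-1] ** 2 / desk[-1] ** 2 == 64

    def test_six_blocks_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="six"):
            ModelConfig(block_channels=(8, 16, 32))
        with pytest.raises(ValueError, match="increasing"):
            ModelConfig(block_channels=(64, 64, 128, 256, 512, 1024))


class TestForward:
    def test_length_invariance(self, tiny_model_config, rng):
        """500- and 1000-frame inputs produce embeddings of the same
        dimension — global pooling absorbs the frame count."""
        model = CNN14(tiny_model_config, seed=0)
        model.eval()
        e_short = model.embed(rng.normal(size=(1, 500, 64)).astype(np.float32))
        e_long = model.embed(rng.normal(size=(1, 1000, 64)).astype(np.float32))
        assert e_short.shape == e_long.shape == (1, 16)

    def test_eval_mode_is_deterministic(self, tiny_model_config, rng):
        model = CNN14(tiny_model_config, seed=0)
        model.eval()
        x = rng.normal(size=(2, 96, 64)).astype(np.float32)
        np.testing.assert_array_equal(model.classify(x), model.classify(x))

    def test_scores_are_sigmoid_bounded(self, tiny_model_config, rng):
        model = CNN14(tiny_model_config, seed=0)
        scores = model.classify(rng.normal(size=(3, 64, 64)).astype(np.float32))
        assert scores.shape == (3, 2)
        assert np.all((scores > 0) & (scores < 1))

    def test_zeroed_head_scores_one_half(self, tiny_model_config):
        model = CNN14(tiny_model_config, seed=0)
        model.fc_out.weight.data[:] = 0
        model.fc_out.bias.data[:] = 0
        scores = model.classify(np.zeros((1, 64, 64), dtype=np.float32))
        np.testing.assert_allclose(scores, 0.5)

    def test_tie_predicts_normal(self):
        assert CNN14.predict_label(np.array([[0.5, 0.5]]))[0] == 0
        assert CNN14.predict_label(np.array([[0.2, 0.7]]))[0] == 1

    def test_too_few_frames_raises(self, tiny_model_config):
        model = CNN14(tiny_model_config, seed=0)
        with pytest.raises(ValueError, match="frames"):
            model.classify(np.zeros((1, 63, 64), dtype=np.float32))

    def test_wrong_mel_count_raises(self, tiny_model_config):
        model = CNN14(tiny_model_config, seed=0)
        with pytest.raises(ValueError, match="64"):
            model.classify(np.zeros((1, 64, 32), dtype=np.float32))


class TestCheckpoints:
    def test_round_trip_preserves_outputs(self, tiny_model_config, rng, tmp_path):
        model = CNN14(tiny_model_config, seed=3)
        # move BN stats off their init so the round-trip is non-trivial
        model.train()
        model.embed(rng.normal(size=(4, 64, 64)).astype(np.float32))
        model.eval()
        x = rng.normal(size=(2, 64, 64)).astype(np.float32)
        save_checkpoint(tmp_path / "ck.npz", model, {"epoch": 1})
        back = load_checkpoint(tmp_path / "ck.npz", expected_config=tiny_model_config)
        back.eval()
        np.testing.assert_allclose(back.classify(x), model.classify(x), atol=1e-6)

    def test_config_mismatch_raises(self, tiny_model_config, tmp_path):
        model = CNN14(tiny_model_config, seed=0)
        save_checkpoint(tmp_path / "ck.npz", model)
        with pytest.raises(ValueError, match="config"):
            load_checkpoint(tmp_path / "ck.npz", expected_config=ModelConfig(width_scale=16))

    def test_external_key_mapping_imports_backbone(self, tiny_model_config, rng, tmp_path):
        """A synthetic stand-in for an externally pre-trained backbone
        checkpoint (external key naming, torch Linear orientation) loads into
        the right parameters."""
        donor = CNN14(tiny_model_config, seed=9)
        arrays = {}
        for i, block in enumerate(donor.blocks):
            pre = f"conv_block{i + 1}"
            for j, conv, bn in ((1, block.conv1, block.bn1), (2, block.conv2, block.bn2)):
                arrays[f"{pre}.conv{j}.weight"] = conv.weight.data
                arrays[f"{pre}.conv{j}.bias"] = conv.bias.data
                arrays[f"{pre}.bn{j}.weight"] = bn.gamma.data
                arrays[f"{pre}.bn{j}.bias"] = bn.beta.data
        arrays["fc1.weight"] = donor.fc_embed.weight.data.T  # (out, in) convention
        arrays["fc1.bias"] = donor.fc_embed.bias.data
        np.savez(tmp_path / "external.npz", **arrays)

        loaded = load_external_checkpoint(tmp_path / "external.npz", tiny_model_config)
        np.testing.assert_array_equal(
            loaded.blocks[2].conv1.weight.data, donor.blocks[2].conv1.weight.data
        )
        np.testing.assert_array_equal(loaded.fc_embed.weight.data, donor.fc_embed.weight.data)
        # classification head stays freshly initialized, not imported
        assert not np.array_equal(loaded.fc_out.weight.data, donor.fc_out.weight.data)

    def test_external_checkpoint_without_known_keys_raises(self, tiny_model_config, tmp_path):
        np.savez(tmp_path / "junk.npz", foo=np.zeros(3))
        with pytest.raises(ValueError, match="no recognized"):
            load_external_checkpoint(tmp_path / "junk.npz", tiny_model_config)
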