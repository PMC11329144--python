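"""Training arms: schedules, reproducibility, and learning on tiny fixtures."""

import dataclasses

import numpy as np
import pytest

from bruitnet.features import MelConfig
from bruitnet.labeling import LabeledRecording
from bruitnet.synth import RecordingRecord, SynthConfig, generate_recording
from bruitnet.train import (
    FinetuneConfig,
    PretrainConfig,
    checkpoint_epochs,
    pretrain_contrastive,
    train_supervised,
)
import datetime as dt

#: 64 frames for a 20-s segment — the smallest valid model input
COARSE_MEL = MelConfig(window_s=0.128, hop_s=0.3125)
#: 64 frames for a 5-s crop
CROP_MEL = MelConfig(window_s=0.128, hop_s=0.078125)

SYNTH = SynthConfig(duration=21.0)


def _records(n, seed0=0, states=None):
    day = dt.date(2021, 1, 1)
    out = []
    for i in range(n):
        state = states[i] if states else ("stenotic" if i % 2 else "patent")
        wav = generate_recording(SYNTH, state, seed0 + i)
        out.append(
            RecordingRecord(f"P{i:03d}", day + dt.timedelta(days=i), "arterial", None, state, wav)
        )
    return out


@pytest.fixture(scope="module")
def labeled_20():
    recs = _records(20)
    return [
        LabeledRecording(r, "abnormal" if r.truth_state == "stenotic" else "normal")
        for r in recs
    ]


class TestSchedules:
    def test_paper_checkpoint_schedule(self):
        assert len(checkpoint_epochs(200, 10)) == 20
        assert checkpoint_epochs(5, 2) == [2, 4]

    def test_epochs_resolve_from_init(self):
        assert FinetuneConfig(init="scratch").resolved_epochs == 40
        assert FinetuneConfig(init="contrastive_checkpoint").resolved_epochs == 20
        assert FinetuneConfig(init="external_checkpoint").resolved_epochs == 20
        assert FinetuneConfig(init="scratch", epochs=6).resolved_epochs == 6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FinetuneConfig(init="imagenet")
        with pytest.raises(ValueError):
            PretrainConfig(batch_n=1)
        with pytest.raises(ValueError):
            PretrainConfig(tau=0.0)


class TestPretrain:
    def test_loss_decreases_on_synthetic_unlabeled(self, tiny_model_config):
        recs = _records(40, seed0=100)
        p = PretrainConfig(batch_n=8, epochs=3, checkpoint_every=3, lr=1e-3, seed=0)
        _, log = pretrain_contrastive(recs, p, tiny_model_config, CROP_MEL)
        assert len(log) == 3
        assert log[-1]["loss"] < log[0]["loss"]

    def test_checkpoints_written_and_selected(self, tiny_model_config, tmp_path):
        recs = _records(24, seed0=200)
        p = PretrainConfig(batch_n=8, epochs=4, checkpoint_every=2, lr=1e-3, seed=0)
        model, log = pretrain_contrastive(recs, p, tiny_model_config, CROP_MEL, tmp_path)
        assert (tmp_path / "pretrain_epoch0002.npz").exists()
        assert (tmp_path / "pretrain_epoch0004.npz").exists()
        assert (tmp_path / "pretrain_selected.npz").exists()
        assert (tmp_path / "pretrain_log.csv").exists()

    def test_same_seed_reproduces_loss_trace(self, tiny_model_config):
        recs = _records(20, seed0=300)
        p = PretrainConfig(batch_n=8, epochs=2, checkpoint_every=2, lr=1e-3, seed=5)
        _, log1 = pretrain_contrastive(recs, p, tiny_model_config, CROP_MEL)
        _, log2 = pretrain_contrastive(recs, p, tiny_model_config, CROP_MEL)
        assert [e["loss"] for e in log1] == pytest.approx([e["loss"] for e in log2], rel=1e-6)

    def test_insufficient_data_raises(self, tiny_model_config):
        with pytest.raises(ValueError, match="unlabeled"):
            pretrain_contrastive(_records(4), PretrainConfig(batch_n=8), tiny_model_config)


class TestSupervised:
    def test_reaches_full_training_accuracy_on_separable_set(
        self, tiny_model_config, labeled_20
    ):
        """The spectrally separable 20-recording fixture is fit to 100%
        training accuracy within the scratch epoch budget."""
        cfg = FinetuneConfig(init="scratch", lr=1e-3, seed=0)
        model = train_supervised(labeled_20, cfg, tiny_model_config, COARSE_MEL)
        from bruitnet.train import _middle_spec

        specs = np.stack([_middle_spec(lr.record, COARSE_MEL) for lr in labeled_20])
        preds = model.predict_label(model.classify(specs))
        truth = np.array([1 if lr.label == "abnormal" else 0 for lr in labeled_20])
        assert np.mean(preds == truth) == 1.0

    def test_single_class_raises(self, tiny_model_config):
        recs = _records(6, states=["patent"] * 6)
        labeled = [LabeledRecording(r, "normal") for r in recs]
        with pytest.raises(ValueError, match="both classes"):
            train_supervised(labeled, FinetuneConfig(epochs=1), tiny_model_config, COARSE_MEL)

    def test_scratch_rejects_checkpoint(self, tiny_model_config, labeled_20):
        with pytest.raises(ValueError, match="scratch"):
            train_supervised(
                labeled_20,
                FinetuneConfig(init="scratch", epochs=1),
                tiny_model_config,
                COARSE_MEL,
                init_checkpoint="whatever.npz",
            )

    def test_checkpoint_arm_requires_checkpoint(self, tiny_model_config, labeled_20):
        with pytest.raises(ValueError, match="requires a checkpoint"):
            train_supervised(
                labeled_20,
                FinetuneConfig(init="contrastive_checkpoint", epochs=1),
                tiny_model_config,
                COARSE_MEL,
            )

    def test_finetune_from_external_checkpoint_file(
        self, tiny_model_config, labeled_20, tmp_path
    ):
        """A backbone checkpoint in the external naming convention initializes
        the external-pre-training arm end to end."""
        from bruitnet.model import CNN14

        donor = CNN14(tiny_model_config, seed=11)
        arrays = {}
        for i, block in enumerate(donor.blocks):
            for j, conv in ((1, block.conv1), (2, block.conv2)):
                arrays[f"conv_block{i + 1}.conv{j}.weight"] = conv.weight.data
                arrays[f"conv_block{i + 1}.conv{j}.bias"] = conv.bias.data
        np.savez(tmp_path / "external.npz", **arrays)
        cfg = FinetuneConfig(init="external_checkpoint", epochs=1, lr=1e-3, seed=0)
        model = train_supervised(
            labeled_20, cfg, tiny_model_config, COARSE_MEL,
            init_checkpoint=tmp_path / "external.npz",
        )
        specs = model.classify(
            np.zeros((2, 64, 64), dtype=np.float32)
        )
        assert specs.shape == (2, 2)

    def test_finetune_from_contrastive_model_object(self, tiny_model_config, labeled_20):
        from bruitnet.model import CNN14

        donor = CNN14(tiny_model_config, seed=7)
        cfg = FinetuneConfig(init="contrastive_checkpoint", epochs=2, lr=1e-3, seed=0)
        model = train_supervised(
            labeled_20, cfg, tiny_model_config, COARSE_MEL, init_checkpoint=donor
        )
        # fine-tuning trains all layers: backbone weights moved
        assert not np.array_equal(
            model.blocks[0].conv1.weight.data, donor.blocks[0].conv1.weight.data
        )
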