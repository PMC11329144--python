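"""The CNN14 backbone for bruit classification.

Six convolution blocks — each two (3x3 conv, batch-norm, ReLU) layers followed
by 2x2 max-pooling — over a ``frames x 64`` log-mel spectrogram, then global
pooling (average of time–frequency mean and max), a fully connected embedding
layer with ReLU, and a 2-unit sigmoid classification head (normal, abnormal).
Global pooling makes the network length-invariant, so 5-second crops and
20-second segments share one architecture; any input with >= 64 frames (the
minimum surviving six poolings) is valid.

A ``width_scale`` divisor shrinks every channel count for desk-scale CPU
experiments without changing the layer structure.  An optional SimCLR-style
projection head is used only during contrastive pre-training and discarded
before fine-tuning.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .features import MelSpectrogram
from .nn import BatchNorm2d, Conv3x3, Linear, Module, Tensor, maxpool2x2, no_grad

__all__ = ["ModelConfig", "CNN14", "load_checkpoint", "save_checkpoint", "load_external_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``block_channels`` are the six per-block output channel counts at full
    width; ``width_scale`` divides all of them (and the embedding/projection
    dims) for desk profiles.
    """

    block_channels: tuple[int, ...] = (64, 128, 256, 512, 1024, 2048)
    embed_dim: int = 2048
    n_outputs: int = 2
    width_scale: int = 1
    projection_head: bool = True
    projection_dims: tuple[int, int] = (512, 128)

    def __post_init__(self) -> None:
        if len(self.block_channels) != 6:
            raise ValueError("the backbone has exactly six convolution blocks")
        if any(a >= b for a, b in zip(self.block_channels, self.block_channels[1:])):
            raise ValueError("block channels must be strictly increasing")
        if self.width_scale < 1:
            raise ValueError("width_scale must be >= 1")

    def _scaled(self, c: int) -> int:
        return max(1, c // self.width_scale)

    @property
    def scaled_channels(self) -> tuple[int, ...]:
        return tuple(self._scaled(c) for c in self.block_channels)

    @property
    def scaled_embed_dim(self) -> int:
        return self._scaled(self.embed_dim)

    @property
    def scaled_projection_dims(self) -> tuple[int, int]:
        return tuple(self._scaled(d) for d in self.projection_dims)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


class _ConvBlock(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv3x3(c_in, c_out, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv3x3(c_out, c_out, rng)
        self.bn2 = BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        x = self.bn2(self.conv2(x)).relu()
        return maxpool2x2(x)


class CNN14(Module):
    """The backbone with classification head and embedding/projection taps."""

    MIN_FRAMES = 64

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        chans = config.scaled_channels
        self.blocks = [
            _ConvBlock(c_in, c_out, rng)
            for c_in, c_out in zip((1,) + chans[:-1], chans)
        ]
        self.fc_embed = Linear(chans[-1], config.scaled_embed_dim, rng)
        self.fc_out = Linear(config.scaled_embed_dim, config.n_outputs, rng)
        if config.projection_head:
            d1, d2 = config.scaled_projection_dims
            self.proj1 = Linear(config.scaled_embed_dim, d1, rng)
            self.proj2 = Linear(d1, d2, rng)

    # -- forward paths -----------------------------------------------------

    @staticmethod
    def _as_batch(spec) -> np.ndarray:
        """Accept a MelSpectrogram, a (frames, 64) array, or a batch thereof."""
        if isinstance(spec, MelSpectrogram):
            arr = spec.values[None]
        else:
            arr = np.asarray(spec, dtype=np.float32)
            if arr.ndim == 2:
                arr = arr[None]
        if arr.ndim != 3 or arr.shape[2] != 64:
            raise ValueError(f"expected (batch, frames, 64) input, got shape {arr.shape}")
        if arr.shape[1] < CNN14.MIN_FRAMES:
            raise ValueError(
                f"need >= {CNN14.MIN_FRAMES} frames to survive six 2x2 poolings, "
                f"got {arr.shape[1]}"
            )
        return arr

    def embed(self, spec) -> Tensor:
        """Backbone embedding: (batch, embed_dim), after global pooling + FC/ReLU."""
        arr = self._as_batch(spec)
        x = Tensor(arr[:, None, :, :])  # (N, 1, frames, mels)
        for block in self.blocks:
            x = block(x)
        n, c = x.shape[0], x.shape[1]
        flat = x.reshape(n, c, x.shape[2] * x.shape[3])
        pooled = (flat.mean(axis=2) + flat.max(axis=2)) * 0.5
        return self.fc_embed(pooled).relu()

    def project(self, emb: Tensor) -> Tensor:
        """Projection-head output used for the contrastive loss."""
        if not self.config.projection_head:
            return emb
        return self.proj2(self.proj1(emb).relu())

    def classify_logits(self, spec) -> Tensor:
        return self.fc_out(self.embed(spec))

    def classify(self, spec) -> np.ndarray:
        """Per-class sigmoid scores, shape (batch, 2), computed in eval mode."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                scores = self.classify_logits(spec).sigmoid().data
        finally:
            if was_training:
                self.train()
        return scores

    @staticmethod
    def predict_label(scores: np.ndarray) -> np.ndarray:
        """Argmax with ties resolved to normal (class 0)."""
        scores = np.atleast_2d(scores)
        return (scores[:, 1] > scores[:, 0]).astype(int)

    # -- introspection -----------------------------------------------------

    def architecture_summary(self) -> list[str]:
        """One row per layer, mirroring the backbone table."""
        rows = []
        for block in self.blocks:
            c = block.conv1.out_channels
            rows.append(f"conv3x3 @ {c} (BN, ReLU) x 2")
            rows.append("maxpool 2x2")
        rows.append("global pooling")
        rows.append(f"fc {self.fc_embed.out_features} (ReLU)")
        rows.append(f"fc {self.fc_out.out_features} (sigmoid)")
        return rows

    def backbone_parameter_names(self) -> list[str]:
        """Parameters excluding the projection head (kept across fine-tuning)."""
        return [k for k in self.named_parameters() if not k.startswith("proj")]


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(path: str | Path, model: CNN14, meta: dict | None = None) -> None:
    """Self-describing ``.npz`` checkpoint: weights, BN buffers, config, metadata."""
    arrays = {f"param/{k}": v.data for k, v in model.named_parameters().items()}
    for i, block in enumerate(model.blocks):
        for bn_name in ("bn1", "bn2"):
            bn = getattr(block, bn_name)
            arrays[f"buffer/blocks.{i}.{bn_name}.running_mean"] = bn.running_mean
            arrays[f"buffer/blocks.{i}.{bn_name}.running_var"] = bn.running_var
    header = {
        "config": asdict(model.config),
        "config_hash": model.config.config_hash(),
        "meta": meta or {},
    }
    np.savez(str(path), __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path, expected_config: ModelConfig | None = None) -> CNN14:
    """Rebuild a model from a checkpoint; verifies the config hash if given."""
    with np.load(str(path)) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        cfg_dict = header["config"]
        for key in ("block_channels", "projection_dims"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        if expected_config is not None and config != expected_config:
            raise ValueError(
                f"checkpoint config {config} does not match expected {expected_config}"
            )
        model = CNN14(config)
        params = model.named_parameters()
        for key in data.files:
            if key.startswith("param/"):
                name = key[len("param/") :]
                if name not in params:
                    raise ValueError(f"unexpected parameter {name} in checkpoint")
                if params[name].data.shape != data[key].shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = data[key].astype(np.float32)
        for i, block in enumerate(model.blocks):
            for bn_name in ("bn1", "bn2"):
                bn = getattr(block, bn_name)
                bn.running_mean = data[f"buffer/blocks.{i}.{bn_name}.running_mean"].astype(np.float32)
                bn.running_var = data[f"buffer/blocks.{i}.{bn_name}.running_var"].astype(np.float32)
    return model


#: mapping from external PANNs-style checkpoint keys to this package's
#: parameter names (torch Linear weights are (out, in) and are transposed on
#: import; conv weights share the (O, C, 3, 3) layout).
EXTERNAL_KEY_MAP: dict[str, str] = {}
for _i in range(6):
    _ours = f"blocks.{_i}"
    _theirs = f"conv_block{_i + 1}"
    for _j in (1, 2):
        EXTERNAL_KEY_MAP[f"{_theirs}.conv{_j}.weight"] = f"{_ours}.conv{_j}.weight"
        EXTERNAL_KEY_MAP[f"{_theirs}.conv{_j}.bias"] = f"{_ours}.conv{_j}.bias"
        EXTERNAL_KEY_MAP[f"{_theirs}.bn{_j}.weight"] = f"{_ours}.bn{_j}.gamma"
        EXTERNAL_KEY_MAP[f"{_theirs}.bn{_j}.bias"] = f"{_ours}.bn{_j}.beta"
EXTERNAL_KEY_MAP["fc1.weight"] = "fc_embed.weight"
EXTERNAL_KEY_MAP["fc1.bias"] = "fc_embed.bias"


def load_external_checkpoint(path: str | Path, config: ModelConfig, seed: int = 0) -> CNN14:
    """Initialize a model from an externally supplied backbone checkpoint.

    The file is an ``.npz`` whose keys follow the external naming convention
    in :data:`EXTERNAL_KEY_MAP` (e.g. ``conv_block1.conv1.weight``).  Layers
    not present in the map — the classification head, and the projection head
    — keep their fresh initialization.  Running BN statistics are imported
    when provided under ``<block>.bn<j>.running_mean/var``.
    """
    model = CNN14(config, seed=seed)
    params = model.named_parameters()
    with np.load(str(path)) as data:
        found = 0
        for ext_key, our_key in EXTERNAL_KEY_MAP.items():
            if ext_key not in data.files:
                continue
            arr = data[ext_key].astype(np.float32)
            if our_key.endswith("fc_embed.weight"):
                arr = arr.T  # torch Linear stores (out, in)
            if params[our_key].data.shape != arr.shape:
                raise ValueError(
                    f"external key {ext_key}: shape {arr.shape} != {params[our_key].data.shape}"
                )
            params[our_key].data = arr
            found += 1
        if found == 0:
            raise ValueError(f"{path}: no recognized external checkpoint keys")
        for i, block in enumerate(model.blocks):
            for j, bn in ((1, block.bn1), (2, block.bn2)):
                mean_key = f"conv_block{i + 1}.bn{j}.running_mean"
                var_key = f"conv_block{i + 1}.bn{j}.running_var"
                if mean_key in data.files:
                    bn.running_mean = data[mean_key].astype(np.float32)
                if var_key in data.files:
                    bn.running_var = data[var_key].astype(np.float32)
    return model
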