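"""The three training arms.

* ``pretrain_contrastive`` — self-supervised pre-training on unlabeled
  recordings: each minibatch recording is randomly truncated into two short
  crops (audio domain), both are embedded through the backbone (and optional
  projection head), and the InfoNCE loss pulls the two crops of a recording
  together while pushing other recordings apart.
* ``train_supervised`` — supervised training on the labeled recordings'
  middle-20-s segments with one-hot binary cross-entropy over the two sigmoid
  outputs; no augmentation.  Initialization is one of: random (scratch), an
  externally supplied backbone checkpoint, or the contrastive checkpoint.

Default hyperparameters follow the study protocol: contrastive pre-training
for 200 epochs, batch 64, Adam at 1e-4, checkpointed every 10 epochs;
supervised training for 40 epochs from scratch or 20 epochs from any
pre-trained initialization, batch 16, Adam at 1e-4.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .audio import Waveform, middle_segment, random_crops, read_wav
from .features import MelConfig, melspec
from .labeling import LabeledRecording
from .losses import bce_loss_graph, infonce_loss_graph
from .model import CNN14, ModelConfig, load_checkpoint, save_checkpoint, load_external_checkpoint
from .nn import Adam, no_grad
from .synth import RecordingRecord

__all__ = [
    "PretrainConfig",
    "FinetuneConfig",
    "pretrain_contrastive",
    "train_supervised",
    "checkpoint_epochs",
]

logger = logging.getLogger(__name__)

CLASS_INDEX = {"normal": 0, "abnormal": 1}


@dataclass(frozen=True)
class PretrainConfig:
    batch_n: int = 64          # recordings per minibatch (2N crops)
    epochs: int = 200
    checkpoint_every: int = 10
    lr: float = 1e-4
    tau: float = 0.5
    crop_s: float = 5.0
    val_fraction: float = 0.1  # held-out unlabeled split for checkpoint selection
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_n < 2:
            raise ValueError("contrastive batches need at least 2 recordings")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class FinetuneConfig:
    """``epochs=None`` resolves from ``init``: 40 from scratch, 20 otherwise."""

    epochs: Optional[int] = None
    batch: int = 16
    lr: float = 1e-4
    init: str = "scratch"  # scratch | external_checkpoint | contrastive_checkpoint
    seed: int = 0

    def __post_init__(self) -> None:
        if self.init not in ("scratch", "external_checkpoint", "contrastive_checkpoint"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.epochs is not None and self.epochs <= 0:
            raise ValueError("epochs must be positive")

    @property
    def resolved_epochs(self) -> int:
        if self.epochs is not None:
            return self.epochs
        return 40 if self.init == "scratch" else 20


def checkpoint_epochs(epochs: int, checkpoint_every: int) -> list[int]:
    """1-based epoch indices at which a pre-training checkpoint is written."""
    return [e for e in range(1, epochs + 1) if e % checkpoint_every == 0]


def _waveform_of(record: RecordingRecord) -> Waveform:
    if record.waveform is not None:
        return record.waveform
    if record.path is None:
        raise ValueError(f"record {record.patient_id}/{record.timestamp} has no audio")
    return read_wav(record.path)


def _middle_spec(record: RecordingRecord, mel_cfg: MelConfig, cache: dict | None = None):
    key = (record.patient_id, record.timestamp)
    if cache is not None and key in cache:
        return cache[key]
    spec = melspec(middle_segment(_waveform_of(record)), mel_cfg).values.astype(np.float32)
    if cache is not None:
        cache[key] = spec
    return spec


def pretrain_contrastive(
    unlabeled: list[RecordingRecord],
    p: PretrainConfig,
    m: ModelConfig,
    mel_cfg: MelConfig = MelConfig(),
    out_dir: str | Path | None = None,
) -> tuple[CNN14, list[dict]]:
    """Contrastive pre-training on unlabeled recordings.

    Per epoch: shuffle recordings, form minibatches of ``batch_n`` (the last
    incomplete minibatch is dropped), take two random crops of each
    recording's middle-20-s segment, embed both through the projection head,
    and minimize the InfoNCE loss with Adam.  A checkpoint is written every
    ``checkpoint_every`` epochs; the returned model is the checkpoint with
    the lowest validation loss on a held-out unlabeled split, and the log (one
    dict per epoch: running/validation loss) is returned alongside.
    """
    if len(unlabeled) < p.batch_n:
        raise ValueError(
            f"need >= batch_n={p.batch_n} unlabeled recordings, got {len(unlabeled)}"
        )
    rng = np.random.default_rng(p.seed)
    model = CNN14(m, seed=int(rng.integers(2**31)))
    model.train()
    optimizer = Adam(model.parameters(), lr=p.lr)

    n_val = max(2, int(round(p.val_fraction * len(unlabeled)))) if len(unlabeled) - p.batch_n >= 2 else 0
    order = rng.permutation(len(unlabeled))
    val_records = [unlabeled[i] for i in order[:n_val]]
    train_records = [unlabeled[i] for i in order[n_val:]]
    if len(train_records) < p.batch_n:
        train_records = list(unlabeled)
        val_records = []

    cache: dict = {}
    segments = {  # middle-20-s segment per record, crops drawn per (epoch, record)
        i: middle_segment(_waveform_of(r)) for i, r in enumerate(unlabeled)
    }
    index_of = {id(r): i for i, r in enumerate(unlabeled)}

    def batch_specs(records: list[RecordingRecord], epoch: int) -> np.ndarray:
        specs = []
        for r in records:
            i = index_of[id(r)]
            crop_seed = int(rng.integers(2**31)) if epoch >= 0 else 12345 + i
            for crop in random_crops(segments[i], p.crop_s, 2, crop_seed):
                specs.append(melspec(crop, mel_cfg).values)
        return np.stack(specs).astype(np.float32)

    def validation_loss(epoch: int) -> float:
        if not val_records:
            return math.nan
        model.eval()
        with no_grad():
            spec = batch_specs(val_records, -1)  # fixed crops -> comparable across epochs
            emb = model.project(model.embed(spec))
        model.train()
        from .losses import infonce_batch_loss

        return infonce_batch_loss(emb.data.astype(np.float64), p.tau)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    log: list[dict] = []
    best = (math.inf, None)  # (val loss, checkpoint epoch)
    checkpoints: dict[int, Path | CNN14] = {}
    for epoch in range(1, p.epochs + 1):
        perm = rng.permutation(len(train_records))
        n_batches = len(train_records) // p.batch_n
        running = 0.0
        for b in range(n_batches):
            batch = [train_records[i] for i in perm[b * p.batch_n : (b + 1) * p.batch_n]]
            spec = batch_specs(batch, epoch)
            emb = model.project(model.embed(spec))
            loss = infonce_loss_graph(emb, p.tau)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite contrastive loss at epoch {epoch}, batch {b}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            running += float(loss.data)
        running /= max(1, n_batches)
        entry = {"epoch": epoch, "loss": running, "val_loss": math.nan}

        if epoch % p.checkpoint_every == 0 or epoch == p.epochs:
            vloss = validation_loss(epoch)
            entry["val_loss"] = vloss
            if out_path is not None:
                ckpt = out_path / f"pretrain_epoch{epoch:04d}.npz"
                save_checkpoint(ckpt, model, {"epoch": epoch, "loss": running, "val_loss": vloss})
                checkpoints[epoch] = ckpt
            score = vloss if not math.isnan(vloss) else running
            if score < best[0]:
                best = (score, epoch)
                if out_path is None:
                    checkpoints[epoch] = _clone_model(model)
        log.append(entry)
        logger.info("pretrain epoch %d: loss %.4f val %.4f", epoch, running, entry["val_loss"])

    if out_path is not None:
        _write_log(out_path / "pretrain_log.csv", log, p.lr)
        if best[1] is not None:
            selected = load_checkpoint(checkpoints[best[1]])
            save_checkpoint(out_path / "pretrain_selected.npz", selected,
                            {"epoch": best[1], "val_loss": best[0]})
            return selected, log
        return model, log
    if best[1] is not None and best[1] in checkpoints:
        return checkpoints[best[1]], log
    return model, log


def _clone_model(model: CNN14) -> CNN14:
    clone = CNN14(model.config)
    src, dst = model.named_parameters(), clone.named_parameters()
    for k in src:
        dst[k].data = src[k].data.copy()
    for b_src, b_dst in zip(model.blocks, clone.blocks):
        for name in ("bn1", "bn2"):
            getattr(b_dst, name).running_mean = getattr(b_src, name).running_mean.copy()
            getattr(b_dst, name).running_var = getattr(b_src, name).running_var.copy()
    return clone


def _write_log(path: Path, log: list[dict], lr: float) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "loss", "val_loss", "lr"])
        for entry in log:
            writer.writerow([entry["epoch"], entry["loss"], entry["val_loss"], lr])


def train_supervised(
    labeled: list[LabeledRecording],
    f: FinetuneConfig,
    m: ModelConfig,
    mel_cfg: MelConfig = MelConfig(),
    init_checkpoint: str | Path | CNN14 | None = None,
    feature_cache: dict | None = None,
) -> CNN14:
    """Supervised training / fine-tuning on middle-20-s segments.

    All layers are trained.  ``init_checkpoint`` must be given (path or model)
    when ``f.init`` names a checkpoint arm, and must be absent for scratch.
    Raises on a single-class training set.
    """
    usable = [lr for lr in labeled if lr.label in CLASS_INDEX]
    classes = {lr.label for lr in usable}
    if classes != set(CLASS_INDEX):
        raise ValueError(f"training set must contain both classes, got {sorted(classes)}")

    if f.init == "scratch":
        if init_checkpoint is not None:
            raise ValueError("init='scratch' does not take a checkpoint")
        model = CNN14(m, seed=f.seed)
    elif init_checkpoint is None:
        raise ValueError(f"init={f.init!r} requires a checkpoint")
    elif isinstance(init_checkpoint, CNN14):
        if init_checkpoint.config != m:
            raise ValueError("checkpoint model config does not match requested config")
        model = _clone_model(init_checkpoint)
    elif f.init == "external_checkpoint":
        model = load_external_checkpoint(init_checkpoint, m, seed=f.seed)
    else:
        model = load_checkpoint(init_checkpoint, expected_config=m)

    rng = np.random.default_rng(f.seed)
    specs = np.stack([_middle_spec(lr.record, mel_cfg, feature_cache) for lr in usable])
    targets = np.zeros((len(usable), 2), dtype=np.float32)
    for i, lr in enumerate(usable):
        targets[i, CLASS_INDEX[lr.label]] = 1.0

    model.train()
    optimizer = Adam(model.parameters(), lr=f.lr)
    n = len(usable)
    for epoch in range(f.resolved_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, f.batch):
            idx = perm[start : start + f.batch]
            if idx.size < 2:
                continue  # batch-norm needs more than one sample
            logits = model.classify_logits(specs[idx])
            loss = bce_loss_graph(logits, targets[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
    model.eval()
    return model
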