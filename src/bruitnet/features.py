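"""Log-mel spectrogram extraction — the network's input representation.

The classifier treats a recording as an image: a ``frames x 64`` matrix of
log-power in 64 mel-spaced frequency bands (HTK mel scale, triangular
filters).  Framing convention: the signal is reflect-padded by half a window
on each side and ``frames = floor(len / hop)`` windows are taken at hop
intervals, so a 10-s clip at 100 frames/s yields exactly 1000 frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .audio import Segment, Waveform

__all__ = ["MelConfig", "MelSpectrogram", "mel_filterbank", "melspec"]


@dataclass(frozen=True)
class MelConfig:
    """STFT and mel-filterbank parameters.

    ``n_mels`` is fixed at 64 by the network's input contract.  ``log_floor``
    (dB) floors the log-power so silence maps to a finite value.
    """

    sample_rate: int = 4000
    n_mels: int = 64
    window_s: float = 0.064
    hop_s: float = 0.010
    fmin: float = 20.0
    fmax: float | None = None
    log_floor: float = -100.0

    def __post_init__(self) -> None:
        if self.n_mels != 64:
            raise ValueError("the model input contract fixes n_mels = 64")
        if self.hop_s <= 0 or self.window_s <= 0:
            raise ValueError("window and hop must be positive")
        if self.effective_fmax > self.sample_rate / 2:
            raise ValueError("fmax exceeds Nyquist")

    @property
    def effective_fmax(self) -> float:
        return self.sample_rate / 2 if self.fmax is None else self.fmax

    @property
    def hop_samples(self) -> int:
        return int(round(self.hop_s * self.sample_rate))

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sample_rate))

    @property
    def n_fft(self) -> int:
        return 1 << (self.window_samples - 1).bit_length()

    @property
    def frame_rate(self) -> float:
        return self.sample_rate / self.hop_samples


@dataclass
class MelSpectrogram:
    """A ``frames x 64`` matrix of floored log-power (dB)."""

    values: np.ndarray
    frame_rate: float
    config: MelConfig = field(repr=False, default=MelConfig())

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, sample_rate: int, fmin: float, fmax: float
) -> np.ndarray:
    """HTK-style triangular mel filterbank, shape ``(n_mels, n_fft // 2 + 1)``.

    Band edges are equally spaced on the HTK mel scale (``2595 log10(1 +
    f/700)``); each filter is a unit-peak triangle evaluated at the FFT bin
    frequencies (no area normalization).
    """
    edges_hz = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, bin_freqs.size))
    for b in range(n_mels):
        lo, ctr, hi = edges_hz[b], edges_hz[b + 1], edges_hz[b + 2]
        up = (bin_freqs - lo) / (ctr - lo)
        down = (hi - bin_freqs) / (hi - ctr)
        fb[b] = np.maximum(0.0, np.minimum(up, down))
    return fb


def melspec(w: Waveform | Segment, cfg: MelConfig = MelConfig()) -> MelSpectrogram:
    """Compute the log-mel spectrogram of a waveform or segment.

    Deterministic; raises on a sample-rate mismatch or an input shorter than
    one hop.
    """
    if w.sample_rate != cfg.sample_rate:
        raise ValueError(
            f"waveform rate {w.sample_rate} != config rate {cfg.sample_rate}"
        )
    x = np.asarray(w.samples, dtype=np.float64)
    hop, win = cfg.hop_samples, cfg.window_samples
    n_frames = x.size // hop
    if n_frames < 1:
        raise ValueError("input shorter than one hop")
    if x.size < win:
        x = np.pad(x, (0, win - x.size))

    pad = win // 2
    xp = np.pad(x, pad, mode="reflect")
    window = np.hanning(win)
    frames = np.lib.stride_tricks.sliding_window_view(xp, win)[:: hop][:n_frames]
    spec = np.fft.rfft(frames * window, n=cfg.n_fft, axis=1)
    power = np.abs(spec) ** 2

    fb = mel_filterbank(cfg.n_mels, cfg.n_fft, cfg.sample_rate, cfg.fmin, cfg.effective_fmax)
    mel_power = power @ fb.T
    floor_power = 10.0 ** (cfg.log_floor / 10.0)
    values = 10.0 * np.log10(np.maximum(mel_power, floor_power))
    return MelSpectrogram(values, cfg.frame_rate, cfg)


def save_melspec(path: str | Path, spec: MelSpectrogram) -> None:
    """Cache a spectrogram as ``.npy`` with a JSON sidecar (shape + config)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), spec.values.astype(np.float32))
    sidecar = {
        "shape": list(spec.values.shape),
        "frame_rate": spec.frame_rate,
        "config": asdict(spec.config),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_melspec(path: str | Path) -> MelSpectrogram:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    values = np.load(path.with_suffix(".npy"))
    if list(values.shape) != sidecar["shape"]:
        raise ValueError(f"cached feature {path} does not match its sidecar")
    return MelSpectrogram(values, sidecar["frame_rate"], MelConfig(**sidecar["config"]))
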