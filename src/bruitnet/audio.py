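"""Waveform containers, PCM16 WAV I/O, and the segment arithmetic used throughout.

Recordings of vascular-access bruit are nominally one minute long; only the
middle 20 seconds are analysed (the head and tail of a hand-held recording
carry probe-placement noise).  All segment arithmetic is 0-based, half-open,
and converts seconds to samples with ``floor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "Segment",
    "read_wav",
    "write_wav",
    "middle_segment",
    "random_crops",
]


@dataclass
class Waveform:
    """A mono audio signal with its sample rate.

    ``samples`` are real-valued in [-1, 1]; values are validated to be finite
    and one-dimensional.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("waveform must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate


@dataclass
class Segment:
    """A half-open sample range ``[start, start + length)`` of a parent waveform."""

    parent: Waveform
    start_sample: int
    length_samples: int

    def __post_init__(self) -> None:
        if self.start_sample < 0 or self.length_samples < 1:
            raise ValueError("segment start must be >= 0 and length >= 1")
        if self.start_sample + self.length_samples > len(self.parent):
            raise ValueError("segment exceeds parent waveform")

    @property
    def samples(self) -> np.ndarray:
        return self.parent.samples[self.start_sample : self.start_sample + self.length_samples]

    @property
    def sample_rate(self) -> int:
        return self.parent.sample_rate

    @property
    def duration(self) -> float:
        return self.length_samples / self.parent.sample_rate


def read_wav(path: str | Path) -> Waveform:
    """Read a mono PCM16 WAV file into a float waveform in [-1, 1)."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype != np.int16:
        raise ValueError(f"{path}: expected PCM16, got dtype {data.dtype}")
    return Waveform(data.astype(np.float64) / 32768.0, int(rate))


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as mono PCM16, refusing clipped input."""
    peak = float(np.max(np.abs(w.samples))) if len(w) else 0.0
    if peak > 1.0:
        raise ValueError(f"refusing to write clipped audio (peak {peak:.3f} > 1.0)")
    data = np.round(w.samples * 32767.0).astype(np.int16)
    wavfile.write(str(path), w.sample_rate, data)


def middle_segment(w: Waveform, length_s: float = 20.0) -> Segment:
    """Extract the centered ``length_s`` seconds of a recording.

    The start index is ``floor((len - length_s * rate) / 2)``; a 1-sample
    asymmetry for odd remainders is tolerated.  Raises ``ValueError`` if the
    recording is shorter than ``length_s``.
    """
    n = int(math.floor(length_s * w.sample_rate))
    if len(w) < n:
        raise ValueError(
            f"recording of {w.duration:.2f} s is shorter than requested {length_s} s"
        )
    start = (len(w) - n) // 2
    return Segment(w, start, n)


def random_crops(seg: Segment, crop_s: float, k: int, seed: int) -> list[Segment]:
    """Draw ``k`` random fixed-length crops of a segment.

    Start positions are uniform over the valid range and reproducible from
    ``seed``.  Used as the audio-domain augmentation for contrastive
    pre-training (two crops of the same recording form a positive pair).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = int(math.floor(crop_s * seg.sample_rate))
    if n > seg.length_samples:
        raise ValueError("crop longer than segment")
    rng = np.random.default_rng(seed)
    max_off = seg.length_samples - n
    offsets = rng.integers(0, max_off + 1, size=k)
    return [Segment(seg.parent, seg.start_sample + int(o), n) for o in offsets]
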