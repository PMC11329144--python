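"""Seeded simulator of arteriovenous-graft blood-flow sounds and patient timelines.

No public dataset of graft bruit exists, so this module generates a corpus with
the statistical structure the detection pipeline assumes:

* each recording is a cardiac-cycle periodic base pulse (band-limited below
  200 Hz) plus an amplitude-modulated band-limited "murmur" whose gain is high
  when the access is stenotic and low when it is patent, plus white sensor
  noise;
* each patient contributes a weekly timeline of recordings; a subset of
  patients develops a stenosis episode, receives a percutaneous transluminal
  angioplasty (PTA) shortly after the last stenotic recording, and reverts to
  a patent access;
* the simulator's ground-truth state is stored per recording but the training
  pipeline only ever sees labels derived from timestamps and PTA dates.

The whole corpus is a pure function of :class:`SynthConfig`, including its seed.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .audio import Waveform, write_wav

__all__ = [
    "SynthConfig",
    "PTAEvent",
    "RecordingRecord",
    "Corpus",
    "generate_recording",
    "generate_corpus",
    "band_energy_ratio",
]

TRUTH_STATES = ("stenotic", "patent")

#: first recording date of every timeline (weekly cadence thereafter)
_EPOCH = dt.date(2020, 9, 14)

#: stenotic weeks per episode before the PTA
_EPISODE_WEEKS = 3

#: days between the last stenotic recording and the PTA intervention
_PTA_LAG_DAYS = 2


@dataclass
class SynthConfig:
    """Parameters of the synthetic corpus.

    Defaults emulate the study cohort: 45 patients on a weekly recording
    cadence, a one-minute recording per visit, and a mostly-unlabeled corpus
    in which roughly half the patients experience a stenosis episode.
    """

    n_patients: int = 45
    recordings_per_patient: int = 15
    sample_rate: int = 4000
    duration: float = 60.0
    stenosis_fraction: float = 0.55
    murmur_band: tuple[float, float] = (300.0, 800.0)
    murmur_gain: float = 0.35
    patent_murmur_fraction: float = 0.25
    heart_rate: float = 1.2
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 2 * self.murmur_band[1]:
            raise ValueError("sample_rate must exceed twice the murmur band's upper edge")
        if self.duration <= 20.0:
            raise ValueError("duration must exceed 20 s (middle-20-s extraction)")
        if self.murmur_gain < 0 or self.noise_sd < 0 or self.patent_murmur_fraction < 0:
            raise ValueError("gains must be non-negative")
        if not (0.0 <= self.stenosis_fraction <= 1.0):
            raise ValueError("stenosis_fraction must be a probability")
        if self.murmur_band[0] <= 200.0:
            raise ValueError("murmur band must sit above the 200 Hz cardiac-pulse band")


@dataclass(frozen=True)
class PTAEvent:
    """A percutaneous transluminal angioplasty intervention for one patient."""

    patient_id: str
    event_date: dt.date


@dataclass
class RecordingRecord:
    """One recording in the corpus manifest.

    ``truth_state`` is the simulator's ground truth ("stenotic"/"patent"); it
    is written to the manifest for auditing but must never be used for
    training — labels come from PTA timelines only.
    """

    patient_id: str
    timestamp: dt.date
    site: str
    path: Optional[Path]
    truth_state: str
    waveform: Optional[Waveform] = field(default=None, repr=False)


@dataclass
class Corpus:
    """A generated corpus: manifest records plus PTA events."""

    records: list[RecordingRecord]
    events: list[PTAEvent]
    config: SynthConfig

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "timestamp": [r.timestamp.isoformat() for r in self.records],
                "site": [r.site for r in self.records],
                "path": [str(r.path) if r.path is not None else "" for r in self.records],
                "truth_state": [r.truth_state for r in self.records],
            }
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [e.patient_id for e in self.events],
                "event_date": [e.event_date.isoformat() for e in self.events],
            }
        )


def _derive_seed(*parts: object) -> int:
    """Stable sub-seed from arbitrary labels; always below 2**31."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


_PULSE_CACHE: dict[tuple[int, int, float], np.ndarray] = {}
_SOS_CACHE: dict[tuple[float, float, int], np.ndarray] = {}


def _cardiac_pulse(n: int, sample_rate: int, heart_rate: float) -> np.ndarray:
    """Periodic cardiac base pulse, strictly band-limited below 200 Hz.

    Built as a harmonic series of the heart rate with exponentially decaying
    amplitudes, truncated at 160 Hz, then scaled to peak 0.5.  Deterministic
    (no random phases) so the zero-noise configuration is exactly periodic.
    Cached per (length, rate, heart rate): every recording in a corpus shares
    the same pulse.
    """
    key = (n, sample_rate, heart_rate)
    if key not in _PULSE_CACHE:
        t = np.arange(n) / sample_rate
        n_harm = max(1, int(160.0 / heart_rate))
        m = np.arange(1, n_harm + 1)
        x = (np.exp(-m / 6.0)[:, None] * np.cos(
            2 * np.pi * heart_rate * m[:, None] * t[None, :] - (m * np.pi / 3)[:, None]
        )).sum(axis=0)
        _PULSE_CACHE[key] = 0.5 * x / np.max(np.abs(x))
        if len(_PULSE_CACHE) > 8:
            _PULSE_CACHE.pop(next(iter(_PULSE_CACHE)))
    return _PULSE_CACHE[key]


def generate_recording(config: SynthConfig, truth_state: str, seed: int) -> Waveform:
    """Synthesize one blood-flow-sound recording.

    The signal is ``pulse + envelope * murmur + white noise``: the murmur is
    band-limited Gaussian noise in ``config.murmur_band``, amplitude-modulated
    by the cardiac envelope (turbulence is strongest in systole), with gain
    ``murmur_gain`` for a stenotic access and ``patent_murmur_fraction`` of it
    for a patent one.  Peak amplitude is normalized to at most 0.9 full scale.
    """
    if truth_state not in TRUTH_STATES:
        raise ValueError(f"truth_state must be one of {TRUTH_STATES}, got {truth_state!r}")
    if config.duration <= 0:
        raise ValueError("duration must be positive")

    sr = config.sample_rate
    n = int(round(config.duration * sr))
    rng = np.random.default_rng(seed)

    base = _cardiac_pulse(n, sr, config.heart_rate)
    x = base.copy()

    gain = config.murmur_gain
    if truth_state == "patent":
        gain *= config.patent_murmur_fraction
    if gain > 0:
        # per-recording intensity jitter so the two classes are distributions,
        # not two fixed waveform families
        gain *= float(np.exp(rng.normal(0.0, 0.15)))
        sos_key = (config.murmur_band[0], config.murmur_band[1], sr)
        if sos_key not in _SOS_CACHE:
            _SOS_CACHE[sos_key] = signal.butter(
                4, config.murmur_band, btype="bandpass", fs=sr, output="sos"
            )
        murmur = signal.sosfiltfilt(_SOS_CACHE[sos_key], rng.standard_normal(n))
        murmur /= np.std(murmur)
        envelope = 0.3 + 0.7 * (base - base.min()) / (base.max() - base.min())
        x = x + gain * envelope * murmur
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal(n)

    peak = np.max(np.abs(x))
    if peak > 0.9:
        x *= 0.9 / peak
    return Waveform(x, sr)


def generate_corpus(
    config: SynthConfig,
    out_dir: str | Path | None = None,
) -> Corpus:
    """Generate the full corpus of timelines, recordings, and PTA events.

    A deterministic ``round(n_patients * stenosis_fraction)`` subset of
    patients (chosen by seeded shuffle) develops one stenosis episode of
    three stenotic weekly recordings; the PTA falls two days after the last
    stenotic recording, and the access is patent afterwards.  If ``out_dir``
    is given, WAV files and ``manifest.csv`` / ``pta_events.csv`` are written
    there; otherwise waveforms are kept in memory on each record.
    """
    if config.n_patients < 1:
        raise ValueError("need at least one patient")
    rpp = config.recordings_per_patient
    if config.stenosis_fraction > 0 and rpp < 8:
        raise ValueError("timelines need >= 8 weekly recordings to host a stenosis episode")

    rng = np.random.default_rng(_derive_seed("corpus", config.seed))
    patients = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]
    n_episodes = int(round(config.n_patients * config.stenosis_fraction))
    order = rng.permutation(config.n_patients)
    episode_patients = {patients[i] for i in order[:n_episodes]}

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "wav").mkdir(parents=True, exist_ok=True)

    records: list[RecordingRecord] = []
    events: list[PTAEvent] = []
    for pid in patients:
        if pid in episode_patients:
            # episode must leave >= 1 patent recording on each side of the PTA
            w0 = int(rng.integers(3, rpp - _EPISODE_WEEKS - 1))
            stenotic_weeks = set(range(w0, w0 + _EPISODE_WEEKS))
            pta_date = _EPOCH + dt.timedelta(
                days=7 * (w0 + _EPISODE_WEEKS - 1) + _PTA_LAG_DAYS
            )
            events.append(PTAEvent(pid, pta_date))
        else:
            stenotic_weeks = set()

        for week in range(rpp):
            ts = _EPOCH + dt.timedelta(days=7 * week)
            state = "stenotic" if week in stenotic_weeks else "patent"
            wav = generate_recording(config, state, _derive_seed(pid, week, config.seed))
            if out_path is not None:
                wav_file = out_path / "wav" / f"{pid}_{ts.isoformat()}.wav"
                write_wav(wav_file, wav)
                records.append(RecordingRecord(pid, ts, "arterial", wav_file, state))
            else:
                records.append(RecordingRecord(pid, ts, "arterial", None, state, wav))

    corpus = Corpus(records, events, config)
    if out_path is not None:
        corpus.manifest_frame().to_csv(out_path / "manifest.csv", index=False)
        corpus.events_frame().to_csv(out_path / "pta_events.csv", index=False)
    return corpus


def load_corpus(data_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load manifest and PTA-event tables written by :func:`generate_corpus`."""
    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.csv"
    events = data_dir / "pta_events.csv"
    for f in (manifest, events):
        if not f.exists():
            raise FileNotFoundError(f"missing corpus file: {f}")
    return pd.read_csv(manifest), pd.read_csv(events)


def band_energy_ratio(w: Waveform, band: tuple[float, float]) -> float:
    """Welch-periodogram energy in ``band`` relative to the sub-200-Hz pulse band.

    This is the simulator's oracle score: it separates stenotic from patent
    recordings without any learned model, guaranteeing the classification task
    posed to the network is solvable.
    """
    freqs, psd = signal.welch(w.samples, fs=w.sample_rate, nperseg=2048)
    num = np.trapezoid(psd[(freqs >= band[0]) & (freqs <= band[1])],
                       freqs[(freqs >= band[0]) & (freqs <= band[1])])
    den = np.trapezoid(psd[freqs < 200.0], freqs[freqs < 200.0])
    return float(num / den)
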