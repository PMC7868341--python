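"""Synthetic multichannel EEG sessions for closed-loop phase-stimulation testing.

Sessions consist of back-to-back trials (default 11 s each, task window 5-9 s)
of two classes (``MI`` motor imagery / ``rest``), sampled at 1000 Hz over a
27-channel 10/20 montage that always contains C3 and C4.  Every channel
carries 1/f background noise mixed through a fixed full-rank random matrix;
sensorimotor channels additionally carry a narrowband ~10 Hz alpha process
(sinusoid with random-walk phase jitter and slow envelope drift).  During the
task window of ``MI`` trials the contralateral (C4-peaked) alpha envelope is
attenuated by ``1 - erd_depth``, injecting a class-dependent, spatially
structured power difference that downstream spatial filters can recover.

The alpha signal-to-noise ratio is defined *in band*: ``alpha_snr_db`` is the
ratio (dB) of alpha-component power to background-noise power inside the
``alpha_freq +/- 2 Hz`` band at the pattern-peak channel.  This is a stated
default of the generator, not an estimate of any particular dataset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._util import wrap_phase

__all__ = [
    "SynthConfig",
    "Event",
    "EEGRecording",
    "MONTAGE_27",
    "default_montage",
    "generate_session",
    "generate_session_with_truth",
    "generate_pure_alpha",
    "task_windows",
]

#: 27-channel 10/20 montage (sensorimotor strip fully populated).
MONTAGE_27 = (
    "Fp1", "Fp2", "Fz",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P1", "Pz", "P2",
)

# Order used when a reduced montage is requested; C3/C4 always first.
_PRIORITY = (
    "C3", "C4", "Cz", "C1", "C2", "C5", "C6",
    "FC3", "FC4", "FCz", "FC1", "FC2", "FC5", "FC6",
    "CP3", "CP4", "CPz", "CP1", "CP2", "CP5", "CP6",
    "Fp1", "Fp2", "Fz", "P1", "Pz", "P2",
)

# Spatial projection of the two alpha sources onto the montage.
_PATTERN_CONTRA = {"C4": 1.0, "C2": 0.5, "C6": 0.5, "FC4": 0.35, "CP4": 0.35, "Cz": 0.2}
_PATTERN_IPSI = {"C3": 1.0, "C1": 0.5, "C5": 0.5, "FC3": 0.35, "CP3": 0.35, "Cz": 0.2}

CLASSES = ("MI", "rest")
CONDITIONS = ("PMI", "CVS", "RPS", "FPS")


def default_montage(n_channels: int) -> tuple[str, ...]:
    """Return ``n_channels`` 10/20 labels; C3 and C4 are always included."""
    if n_channels == len(MONTAGE_27):
        return MONTAGE_27
    if not 2 <= n_channels <= len(MONTAGE_27):
        raise ValueError(
            f"n_channels must be in [2, {len(MONTAGE_27)}], got {n_channels}"
        )
    return _PRIORITY[:n_channels]


class Event(NamedTuple):
    """One trial: onset sample of the trial, class label, stimulation condition."""

    onset_sample: int
    label: str  # "MI" | "rest"
    condition: str  # "PMI" | "CVS" | "RPS" | "FPS"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic session.

    ``phase_jitter`` is the standard deviation (rad/sample) of the white
    random-walk increments added to the alpha phase; ``envelope_drift`` is the
    relative amplitude of the slow (~0.1 Hz) envelope modulation.
    """

    n_channels: int = 27
    fs: float = 1000.0
    n_trials: int = 40
    trial_len: float = 11.0
    task_window: tuple[float, float] = (5.0, 9.0)
    alpha_freq: float = 10.0
    alpha_snr_db: float = 10.0
    erd_depth: float = 0.5
    noise_exponent: float = 1.0
    phase_jitter: float = 0.02
    envelope_drift: float = 0.2
    condition: str = "FPS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_channels <= len(MONTAGE_27):
            raise ValueError(f"n_channels out of range: {self.n_channels}")
        if self.fs <= 2 * self.alpha_freq:
            raise ValueError("fs must exceed twice the alpha frequency")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.erd_depth < 1:
            raise ValueError(f"erd_depth must be in [0, 1), got {self.erd_depth}")
        lo, hi = self.task_window
        if not (0 <= lo < hi <= self.trial_len):
            raise ValueError(f"task_window {self.task_window} outside [0, {self.trial_len}]")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.phase_jitter < 0 or self.envelope_drift < 0:
            raise ValueError("phase_jitter and envelope_drift must be >= 0")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with a trial event table."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: list[str]
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording (have {self.channel_labels})"
            ) from None
        return self.data[idx]


def task_windows(rec: EEGRecording, task_window: tuple[float, float] = (5.0, 9.0)):
    """Per-trial task-window time spans [(t0, t1), ...] in seconds."""
    lo, hi = task_window
    return [
        (ev.onset_sample / rec.fs + lo, ev.onset_sample / rec.fs + hi)
        for ev in rec.events
    ]


def generate_pure_alpha(
    freq: float, fs: float, duration: float, phase0: float = 0.0
) -> np.ndarray:
    """Exact sinusoid ``sin(2*pi*freq*t + phase0)`` (phase 0 = ascending zero)."""
    if not 0 < freq < fs / 2:
        raise ValueError(f"freq must be in (0, fs/2), got {freq}")
    t = np.arange(round(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase0)


def _pink_noise(rng: np.random.Generator, n_samples: int, exponent: float,
                n_series: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance 1/f^exponent noise rows; also returns the spectral gains."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0)  # normalized; only shape matters
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1) * gain
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out, gain


def _band_fraction(gain: np.ndarray, n_samples: int, fs: float,
                   band: tuple[float, float]) -> float:
    """Fraction of shaped-noise power inside ``band``."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    power = gain**2
    total = power[1:].sum()
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(power[sel].sum() / total)


def _alpha_source(rng: np.random.Generator, cfg: SynthConfig, n_samples: int):
    """Narrowband alpha: random-walk phase + slow envelope drift.

    Returns (signal, unwrapped phase, envelope); signal = envelope * sin(phase).
    """
    incr = 2 * np.pi * cfg.alpha_freq / cfg.fs + cfg.phase_jitter * rng.standard_normal(
        n_samples
    )
    phase0 = rng.uniform(-np.pi, np.pi)
    phase = phase0 + np.cumsum(incr)
    env = np.ones(n_samples)
    if cfg.envelope_drift > 0:
        # ~0.1 Hz drift: smooth on a decimated grid, then interpolate
        fs_slow = 10.0
        n_slow = max(int(np.ceil(n_samples * fs_slow / cfg.fs)) + 2, 8)
        drift = gaussian_filter1d(rng.standard_normal(n_slow), sigma=2.0 * fs_slow,
                                  mode="reflect")
        std = drift.std()
        if std > 0:
            drift /= std
        t_slow = np.arange(n_slow) * (cfg.fs / fs_slow)
        drift = np.interp(np.arange(n_samples), t_slow, drift)
        env = np.clip(1.0 + cfg.envelope_drift * drift, 0.05, None)
    return env * np.sin(phase), phase, env


def _erd_gain(cfg: SynthConfig, events: Sequence[Event], n_samples: int) -> np.ndarray:
    """Multiplicative envelope gain: (1 - erd_depth) inside MI task windows.

    100 ms raised-cosine ramps at the window edges keep the injected power
    change band-limited.
    """
    gain = np.ones(n_samples)
    if cfg.erd_depth == 0:
        return gain
    fs = cfg.fs
    ramp_n = int(round(0.1 * fs))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))  # 0 -> 1
    lo, hi = cfg.task_window
    for ev in events:
        if ev.label != "MI":
            continue
        i0 = ev.onset_sample + int(round(lo * fs))
        i1 = ev.onset_sample + int(round(hi * fs))
        depth = np.full(i1 - i0, cfg.erd_depth)
        depth[:ramp_n] = cfg.erd_depth * ramp
        depth[-ramp_n:] = cfg.erd_depth * ramp[::-1]
        gain[i0:i1] = 1.0 - depth
    return gain


def _mixing_matrix(rng: np.random.Generator, n: int, max_cond: float = 100.0):
    """Random row-normalized full-rank mixing; redrawn until well conditioned."""
    for _ in range(1000):
        m = rng.standard_normal((n, n))
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        if np.linalg.cond(m) <= max_cond:
            return m
    raise RuntimeError("could not draw a well-conditioned mixing matrix")


def _pattern_vector(labels: Sequence[str], weights: dict[str, float]) -> np.ndarray:
    return np.array([weights.get(lab, 0.0) for lab in labels])


def generate_session_with_truth(cfg: SynthConfig):
    """Generate a session and return (recording, ground-truth components).

    The truth dict contains the noiseless alpha components (already scaled and
    ERD-modulated, as added to the pattern-peak channel), the wrapped
    ground-truth alpha phase of the contralateral source, the ERD gain curve,
    the mixed noise, and the spatial patterns/mixing actually used.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = list(default_montage(cfg.n_channels))
    trial_n = int(round(cfg.trial_len * cfg.fs))
    n_samples = cfg.n_trials * trial_n

    # Balanced, randomly ordered class labels.
    half = cfg.n_trials // 2
    classes = np.array(["MI"] * half + ["rest"] * (cfg.n_trials - half))
    classes = classes[rng.permutation(cfg.n_trials)]
    events = [
        Event(i * trial_n, str(classes[i]), cfg.condition) for i in range(cfg.n_trials)
    ]

    mixing = _mixing_matrix(rng, cfg.n_channels)
    pink, gain = _pink_noise(rng, n_samples, cfg.noise_exponent, cfg.n_channels)
    noise = mixing @ pink

    band = (cfg.alpha_freq - 2.0, cfg.alpha_freq + 2.0)
    p_band = _band_fraction(gain, n_samples, cfg.fs, band)
    amp = np.sqrt(2.0 * 10.0 ** (cfg.alpha_snr_db / 10.0) * p_band)

    sig_c, phase_c, env_c = _alpha_source(rng, cfg, n_samples)
    sig_i, phase_i, env_i = _alpha_source(rng, cfg, n_samples)
    erd = _erd_gain(cfg, events, n_samples)

    alpha_contra = amp * erd * sig_c  # as added at the pattern-peak channel (C4)
    alpha_ipsi = amp * sig_i

    pat_c = _pattern_vector(labels, _PATTERN_CONTRA)
    pat_i = _pattern_vector(labels, _PATTERN_IPSI)
    data = noise + np.outer(pat_c, alpha_contra) + np.outer(pat_i, alpha_ipsi)

    rec = EEGRecording(data=data, fs=cfg.fs, channel_labels=labels, events=events)
    truth = {
        "alpha_contra": alpha_contra,
        "alpha_ipsi": alpha_ipsi,
        "phase_contra": wrap_phase(phase_c),
        "phase_ipsi": wrap_phase(phase_i),
        "envelope_contra": env_c,
        "envelope_ipsi": env_i,
        "erd_gain": erd,
        "noise": noise,
        "mixing": mixing,
        "pattern_contra": pat_c,
        "pattern_ipsi": pat_i,
        "alpha_amplitude": amp,
    }
    return rec, truth


def generate_session(cfg: SynthConfig) -> EEGRecording:
    """Generate a fully reproducible synthetic session (see module docstring)."""
    rec, _ = generate_session_with_truth(cfg)
    return rec
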