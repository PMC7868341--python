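"""Phase-gated stimulus scheduling and stimulus waveform synthesis.

A pulse (20 ms, 200 Hz) is emitted whenever the forecast phase enters the
target interval and at least the refractory period (default 100 ms) has
elapsed since the previous pulse.  Pulse amplitudes follow the tic-tic-toc
pattern: every third emitted pulse is 50% stronger.  The open-loop condition
uses a continuous 23 Hz-modulated 200 Hz carrier.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._util import TWO_PI
from .tracker import PhaseEstimate

__all__ = [
    "PhaseInterval",
    "RISING",
    "FALLING",
    "StimulusEvent",
    "phase_in_interval",
    "schedule",
    "synthesize_pulse",
    "synthesize_cvs",
    "save_waveform",
    "AMPLITUDE_PATTERN",
]

#: Tic-tic-toc amplitude cycle over consecutive emitted pulses.
AMPLITUDE_PATTERN = (1.0, 1.0, 1.5)


@dataclass(frozen=True)
class PhaseInterval:
    """Wrap-aware phase arc traversed from ``lo`` to ``hi`` in increasing phase."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.arc_length < TWO_PI:
            raise ValueError(
                f"interval arc must be in (0, 2*pi), got {self.arc_length}"
            )

    @property
    def arc_length(self) -> float:
        return float(np.mod(self.hi - self.lo, TWO_PI))

    def __contains__(self, phi: float) -> bool:
        return phase_in_interval(phi, self)


#: Stimulation intervals bracketing the ascending / descending zero crossings.
RISING = PhaseInterval(-np.pi / 6, np.pi / 3)
FALLING = PhaseInterval(5 * np.pi / 6, 4 * np.pi / 3)


@dataclass
class StimulusEvent:
    """A delivered vibration trigger."""

    onset: float  # s
    duration_ms: float = 20.0
    amplitude_factor: float = 1.0
    mode: str = "FPS"
    realized_phase: float | None = None  # filled in offline


def phase_in_interval(phi, iv: PhaseInterval):
    """True iff ``phi`` lies on the arc from ``iv.lo`` to ``iv.hi`` (inclusive)."""
    dist = np.mod(np.asarray(phi) - iv.lo, TWO_PI)
    return dist <= iv.arc_length + 1e-12


def schedule(
    estimates: Sequence[PhaseEstimate],
    iv: PhaseInterval,
    refractory_ms: float = 100.0,
    mode: str = "FPS",
    window: tuple[float, float] | None = None,
    amplitude_start: int = 0,
) -> list[StimulusEvent]:
    """Convert a time-ordered phase-estimate stream into gated stimulus events.

    Parameters
    ----------
    window : optional (t0, t1)
        When given, only estimates with ``t0 <= t < t1`` may trigger (used to
        restrict stimulation to the per-trial task window).
    amplitude_start : int
        Offset into the tic-tic-toc cycle, for chaining calls.
    """
    ts = [e.t for e in estimates]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("estimates must be time-ordered")
    refractory = refractory_ms / 1000.0
    events: list[StimulusEvent] = []
    last_onset = -np.inf
    count = amplitude_start
    for est in estimates:
        if window is not None and not (window[0] <= est.t < window[1]):
            continue
        if not phase_in_interval(est.phi, iv):
            continue
        if est.t - last_onset < refractory - 1e-12:
            continue
        events.append(
            StimulusEvent(
                onset=est.t,
                duration_ms=20.0,
                amplitude_factor=AMPLITUDE_PATTERN[count % len(AMPLITUDE_PATTERN)],
                mode=mode,
            )
        )
        count += 1
        last_onset = est.t
    return events


def _raised_cosine_ramps(n: int, ramp_n: int) -> np.ndarray:
    env = np.ones(n)
    ramp_n = min(ramp_n, n // 2)
    if ramp_n > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] = r
        env[-ramp_n:] = r[::-1]
    return env


def synthesize_pulse(
    duration_ms: float = 20.0,
    carrier: float = 200.0,
    amplitude_factor: float = 1.0,
    out_fs: float = 8000.0,
    ramp_ms: float = 2.0,
) -> np.ndarray:
    """A 200 Hz tone burst with raised-cosine on/off ramps."""
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration_ms / 1000.0 * out_fs))
    t = np.arange(n) / out_fs
    tone = np.sin(2 * np.pi * carrier * t)
    env = _raised_cosine_ramps(n, int(round(ramp_ms / 1000.0 * out_fs)))
    return amplitude_factor * env * tone


def synthesize_cvs(
    duration: float,
    mod: float = 23.0,
    carrier: float = 200.0,
    out_fs: float = 8000.0,
) -> np.ndarray:
    """Continuous open-loop waveform: 23 Hz envelope on a 200 Hz carrier.

    Envelope modulation ``m(t) = (1 + sin(2*pi*mod*t)) / 2`` (non-negative,
    suitable to drive a voice-coil tactor), giving spectral lines at the
    carrier and carrier +/- mod.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * out_fs))
    t = np.arange(n) / out_fs
    m = 0.5 * (1.0 + np.sin(2 * np.pi * mod * t))
    return m * np.sin(2 * np.pi * carrier * t)


def save_waveform(path, waveform: np.ndarray, out_fs: float = 8000.0) -> None:
    """Write a waveform as 16-bit PCM WAV (peak-normalized above full scale)."""
    from scipy.io import wavfile

    w = np.asarray(waveform, dtype=float)
    peak = np.abs(w).max()
    if peak > 1.0:
        w = w / peak
    wavfile.write(path, int(out_fs), np.round(w * 32767).astype(np.int16))
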