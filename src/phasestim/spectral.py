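"""Trial-averaged ERSP, band ERD summaries, and sliding band-energy curves.

ERSP: per-trial short-time Fourier power (200 ms Hann window), averaged over
trials in the linear-power domain, converted to dB, then baseline-normalized
by subtracting the per-frequency mean over the [3, 4] s pre-cue window (dB
subtraction, i.e. a log power ratio).  Time 0 is the trial start; the task
starts at 5 s.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import next_pow2
from .synth import EEGRecording

__all__ = [
    "ERSPMap",
    "BandEnergyCurve",
    "ersp",
    "band_erd",
    "band_energy_curve",
    "car_reference",
    "ALPHA_BAND",
    "BETA_BAND",
]

ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (14.0, 30.0)


@dataclass
class ERSPMap:
    """Baseline-normalized time-frequency power change (dB)."""

    values: np.ndarray  # (n_freqs, n_times), dB
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s, window centres
    channel: str = ""
    n_trials: int = 1
    baseline_window: tuple[float, float] = (3.0, 4.0)


@dataclass
class BandEnergyCurve:
    """Sliding-window band power (linear units) averaged over trials."""

    times: np.ndarray  # s, window centres
    values: np.ndarray
    band: tuple[float, float] = (8.0, 30.0)
    label: str = ""
    condition: str = ""


def _sliding_windows(x2d: np.ndarray, win_n: int, hop_n: int) -> np.ndarray:
    """(n_trials, n_windows, win_n) view over the last axis."""
    n = x2d.shape[-1]
    if n < win_n:
        raise ValueError(f"epoch length {n} shorter than analysis window {win_n}")
    starts = np.arange(0, n - win_n + 1, hop_n)
    idx = starts[:, None] + np.arange(win_n)[None, :]
    return x2d[:, idx], starts


def ersp(
    trials: np.ndarray,
    fs: float,
    win_ms: float = 200.0,
    hop_ms: float = 50.0,
    fmin: float = 1.0,
    fmax: float = 30.0,
    baseline: tuple[float, float] | None = (3.0, 4.0),
    channel: str = "",
) -> ERSPMap:
    """Trial-averaged ERSP of epoched single-channel data.

    Parameters
    ----------
    trials : (n_trials, n_samples)
        Epochs with t = 0 at trial start; must cover the baseline window.
    baseline : (s, s) or None
        Pre-cue window whose per-frequency mean (dB) is subtracted; None
        skips normalization (raw trial-averaged dB power).
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    n_trials, n_samples = trials.shape
    win_n = int(round(win_ms / 1000.0 * fs))
    hop_n = int(round(hop_ms / 1000.0 * fs))
    segs, starts = _sliding_windows(trials, win_n, hop_n)
    times = (starts + (win_n - 1) / 2.0) / fs
    base_cols = None
    if baseline is not None:
        b0, b1 = baseline
        base_cols = (times >= b0) & (times <= b1)
        if not np.any(base_cols):
            raise ValueError(f"baseline window {baseline} not covered by the epochs")

    # Frequency grid at <= 0.5 Hz via zero padding.
    nfft = next_pow2(max(win_n, int(np.ceil(fs / 0.5))))
    taper = np.hanning(win_n)
    spec = np.fft.rfft(segs * taper, nfft, axis=-1)
    power = np.abs(spec) ** 2  # (n_trials, n_windows, n_freqs)
    mean_power = power.mean(axis=0)  # Eq-style trial average in linear power

    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    frow = (freqs >= fmin) & (freqs <= fmax)
    db = 10.0 * np.log10(np.maximum(mean_power[:, frow].T, np.finfo(float).tiny))
    if base_cols is not None:
        db -= db[:, base_cols].mean(axis=1, keepdims=True)
    return ERSPMap(
        values=db,
        freqs=freqs[frow],
        times=times,
        channel=channel,
        n_trials=n_trials,
        baseline_window=baseline,
    )


def band_erd(
    emap: ERSPMap, band: tuple[float, float], window: tuple[float, float]
) -> float:
    """Mean dB change over a frequency-band x time-window rectangle."""
    rows = (emap.freqs >= band[0]) & (emap.freqs <= band[1])
    cols = (emap.times >= window[0]) & (emap.times <= window[1])
    if not np.any(rows) or not np.any(cols):
        raise ValueError(f"empty selection for band {band}, window {window}")
    return float(emap.values[np.ix_(rows, cols)].mean())


def band_energy_curve(
    trials: np.ndarray,
    fs: float,
    band: tuple[float, float] = (8.0, 30.0),
    win_s: float = 1.0,
    hop_s: float = 0.2,
    label: str = "",
    condition: str = "",
) -> BandEnergyCurve:
    """Trial-averaged band power in a sliding window (1 s every 200 ms).

    Band power is the sum of periodogram bins with ``band[0] <= f < band[1]``
    (half-open), so curves over a partition of a band sum exactly to the
    full-band curve.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    win_n = int(round(win_s * fs))
    hop_n = int(round(hop_s * fs))
    segs, starts = _sliding_windows(trials, win_n, hop_n)
    spec = np.fft.rfft(segs, axis=-1)
    power = np.abs(spec) ** 2 / win_n
    freqs = np.fft.rfftfreq(win_n, 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs < band[1])
    if not np.any(sel):
        raise ValueError(f"band {band} contains no frequency bin")
    values = power[:, :, sel].sum(axis=-1).mean(axis=0)
    times = (starts + (win_n - 1) / 2.0) / fs
    return BandEnergyCurve(times=times, values=values, band=band, label=label,
                           condition=condition)


def car_reference(rec: EEGRecording) -> EEGRecording:
    """Common average reference: subtract the per-sample channel mean."""
    if rec.n_channels < 2:
        raise ValueError("CAR needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(
        data=data,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        events=list(rec.events),
    )
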