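"""Offline ground-truth phase and validation of tracking/gating.

The offline oracle is deliberately different from the real-time path: the
bandpass is zero-phase (forward-backward Butterworth), so it has no group
delay, and the phase comes from the analytic signal.  Agreement between the
two is quantified with the phase-locking value (PLV).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig
from scipy.signal import hilbert as _hilbert

from ._util import wrap_phase
from .scheduler import PhaseInterval, StimulusEvent, phase_in_interval
from .synth import EEGRecording

__all__ = [
    "PLVReport",
    "zero_phase_bandpass",
    "hilbert_phase",
    "plv",
    "realized_stimulus_phases",
    "flag_bad_trials",
]


@dataclass(frozen=True)
class PLVReport:
    """Phase-locking value between two phase series.

    ``plv`` = |mean exp(i*(phi_a - phi_b))|; ``circ_mean_error`` is the
    argument of that mean (rad); ``n`` the number of compared time points.
    """

    plv: float
    circ_mean_error: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.plv <= 1 + 1e-12:
            raise ValueError("plv outside [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def zero_phase_bandpass(
    x: np.ndarray, fs: float, band: tuple[float, float], order: int = 4
) -> np.ndarray:
    """Forward-backward Butterworth bandpass (no group delay)."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, fs/2)")
    sos = _sig.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x)


def hilbert_phase(
    x: np.ndarray, fs: float, band: tuple[float, float] = (8.0, 12.0), order: int = 4
) -> np.ndarray:
    """Analytic-signal phase of the bandpassed signal, sine convention.

    Phase 0 falls on the ascending zero crossing (signal ~ sin(phi)); output
    wrapped to [-pi, pi).
    """
    x = np.asarray(x, dtype=float)
    min_len = 12 * order + 1  # sosfiltfilt padding requirement with margin
    if x.size < min_len:
        raise ValueError(f"signal too short for filter settling (need >= {min_len})")
    xf = zero_phase_bandpass(x, fs, band, order=order)
    return wrap_phase(np.angle(_hilbert(xf)) + np.pi / 2)


def plv(phi_a: np.ndarray, phi_b: np.ndarray) -> PLVReport:
    """Phase-locking value and circular mean error between two phase series."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape:
        raise ValueError(f"phase series lengths differ: {phi_a.shape} vs {phi_b.shape}")
    if phi_a.size < 1:
        raise ValueError("need at least one time point")
    z = np.mean(np.exp(1j * (phi_a - phi_b)))
    return PLVReport(plv=float(min(np.abs(z), 1.0)), circ_mean_error=float(np.angle(z)),
                     n=phi_a.size)


def realized_stimulus_phases(
    events: Sequence[StimulusEvent],
    rec: EEGRecording,
    channel: str,
    band: tuple[float, float] = (8.0, 12.0),
    n_bins: int = 24,
):
    """Fill each event's realized phase from the offline Hilbert oracle.

    Returns
    -------
    events_out : list[StimulusEvent]
        Copies of the input events with ``realized_phase`` set.
    counts : ndarray of shape (n_bins,)
        Rose-histogram counts over equal phase bins spanning [-pi, pi);
        counts sum to the number of events.
    bin_edges : ndarray of shape (n_bins + 1,)
    """
    phase = hilbert_phase(rec.channel(channel), rec.fs, band=band)
    events_out = []
    for ev in events:
        idx = int(round(ev.onset * rec.fs))
        if not 0 <= idx < rec.n_samples:
            raise ValueError(f"event onset {ev.onset} s outside recording")
        events_out.append(replace(ev, realized_phase=float(phase[idx])))
    bin_edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    realized = np.array([ev.realized_phase for ev in events_out], dtype=float)
    counts, _ = np.histogram(realized, bins=bin_edges)
    return events_out, counts, bin_edges


def flag_bad_trials(
    trial_events: Mapping[int, Sequence[StimulusEvent]],
    iv: PhaseInterval,
    max_out_fraction: float = 0.5,
) -> tuple[list[int], list[int]]:
    """Split trials into (kept, removed) by mis-placed stimulation fraction.

    A trial is removed when the fraction of its pulses whose realized phase
    falls outside ``iv`` exceeds ``max_out_fraction``.  Trials without pulses
    are kept.
    """
    kept: list[int] = []
    removed: list[int] = []
    for trial_id, events in trial_events.items():
        if len(events) == 0:
            kept.append(trial_id)
            continue
        phases = [ev.realized_phase for ev in events]
        if any(p is None for p in phases):
            raise ValueError(f"trial {trial_id}: realized phases not computed")
        out = sum(0 if phase_in_interval(p, iv) else 1 for p in phases)
        (removed if out / len(events) > max_out_fraction else kept).append(trial_id)
    return kept, removed
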