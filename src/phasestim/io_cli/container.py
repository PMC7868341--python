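"""Array container, delimited tables, and report writers.

All delimited outputs can carry a metadata mapping (config hash, seed) as
leading ``# key=value`` comment lines; JSON reports embed it under ``_meta``.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ..scheduler import StimulusEvent
from ..spectral import ERSPMap
from ..synth import EEGRecording, Event
from ..tracker import PhaseEstimate
from .edf import read_edf

__all__ = [
    "save_recording",
    "load_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_estimates",
    "read_estimates",
    "write_stim_events",
    "read_stim_events",
    "write_ersp",
    "write_matrix",
    "write_json",
]


def _meta_lines(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _read_meta(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


# -- recording container ------------------------------------------------------

def save_recording(path, rec: EEGRecording, meta: Mapping[str, object] | None = None):
    """Save a recording (with events) to a self-describing ``.npz`` container."""
    np.savez(
        path,
        data=rec.data,
        fs=np.array(rec.fs),
        channel_labels=np.array(rec.channel_labels),
        event_onsets=np.array([ev.onset_sample for ev in rec.events], dtype=np.int64),
        event_labels=np.array([ev.label for ev in rec.events]),
        event_conditions=np.array([ev.condition for ev in rec.events]),
        meta=json.dumps(dict(meta or {})),
    )


def load_recording(path) -> EEGRecording:
    with np.load(path, allow_pickle=False) as z:
        events = [
            Event(int(o), str(l), str(c))
            for o, l, c in zip(z["event_onsets"], z["event_labels"],
                               z["event_conditions"])
        ]
        return EEGRecording(
            data=z["data"],
            fs=float(z["fs"]),
            channel_labels=[str(x) for x in z["channel_labels"]],
            events=events,
        )


def read_recording(path) -> EEGRecording:
    """Load EDF (+ ``<stem>.events.tsv`` sidecar) or ``.npz`` container.

    A missing sidecar yields an empty event table with a warning; an ``fs``
    recorded in the sidecar that contradicts the EDF header is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".npz":
        return load_recording(path)
    rec = read_edf(path)
    sidecar = path.with_suffix(".events.tsv")
    if not sidecar.exists():
        warnings.warn(f"no event sidecar {sidecar}; event table left empty")
        return rec
    events, meta = read_events(sidecar)
    if "fs" in meta and float(meta["fs"]) != rec.fs:
        raise ValueError(
            f"fs mismatch: EDF header {rec.fs} Hz vs sidecar {meta['fs']} Hz"
        )
    rec.events = events
    return rec


# -- delimited tables ---------------------------------------------------------

def write_events(path, events: Sequence[Event],
                 meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("onset_sample\tclass\tcondition\n")
        for ev in events:
            fh.write(f"{ev.onset_sample}\t{ev.label}\t{ev.condition}\n")


def read_events(path) -> tuple[list[Event], dict[str, str]]:
    meta = _read_meta(path)
    events = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#") or line.startswith("onset_sample"):
                continue
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{i}: expected 3 fields, got {len(parts)}")
            try:
                events.append(Event(int(parts[0]), parts[1], parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: bad onset_sample {parts[0]!r}") from exc
    return events, meta


def write_estimates(path, estimates: Sequence[PhaseEstimate],
                    meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("t\tphi\tf_dom\ta_dom\n")
        for e in estimates:
            fh.write(f"{e.t:.6f}\t{e.phi:.8f}\t{e.f_dom:.6f}\t{e.a_dom:.8g}\n")


def read_estimates(path) -> list[PhaseEstimate]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "t\t")) or not line.strip():
                continue
            t, phi, f_dom, a_dom = map(float, line.split("\t"))
            out.append(PhaseEstimate(t=t, phi=phi, f_dom=f_dom, a_dom=a_dom))
    return out


def write_stim_events(path, events: Sequence[StimulusEvent],
                      meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write("onset_s\tduration_ms\tamplitude_factor\tmode\trealized_phase\n")
        for ev in events:
            rp = "" if ev.realized_phase is None else f"{ev.realized_phase:.8f}"
            fh.write(
                f"{ev.onset:.6f}\t{ev.duration_ms:g}\t{ev.amplitude_factor:g}"
                f"\t{ev.mode}\t{rp}\n"
            )


def read_stim_events(path) -> list[StimulusEvent]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "onset_s")) or not line.strip():
                continue
            onset, dur, amp, mode, rp = line.rstrip("\n").split("\t")
            out.append(
                StimulusEvent(
                    onset=float(onset),
                    duration_ms=float(dur),
                    amplitude_factor=float(amp),
                    mode=mode,
                    realized_phase=float(rp) if rp else None,
                )
            )
    return out


def write_ersp(path, emap: ERSPMap, meta: Mapping[str, object] | None = None) -> None:
    """ERSP matrix as TSV: first row time axis, first column frequency axis."""
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        fh.write(f"# channel={emap.channel} n_trials={emap.n_trials}\n")
        fh.write("freq_hz\\time_s\t" + "\t".join(f"{t:.3f}" for t in emap.times) + "\n")
        for f, row in zip(emap.freqs, emap.values):
            fh.write(f"{f:.3f}\t" + "\t".join(f"{v:.5f}" for v in row) + "\n")


def write_matrix(path, matrix: np.ndarray, columns: Sequence[str] | None = None,
                 meta: Mapping[str, object] | None = None) -> None:
    """Generic delimited matrix writer (e.g. FBCSP feature tables)."""
    matrix = np.atleast_2d(np.asarray(matrix))
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        if columns is not None:
            if len(columns) != matrix.shape[1]:
                raise ValueError("column count does not match matrix width")
            fh.write("\t".join(columns) + "\n")
        for row in matrix:
            fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")


def write_json(path, payload: dict, meta: Mapping[str, object] | None = None) -> None:
    doc = dict(payload)
    if meta:
        doc["_meta"] = dict(meta)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
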