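"""Minimal EDF (European Data Format) writer/reader for continuous recordings.

Implements the fixed-width ASCII header plus 16-bit little-endian data
records of the EDF specification, which is all this package needs for
interchange.  One data record spans 1 s, so the sampling rate must be an
integer; recordings are zero-padded to a whole number of records on write
(synthetic sessions always have whole-second durations, so round trips are
exact in length and within 16-bit quantization in value).

No EDF library is assumed to be installed; the format's simplicity makes a
self-contained codec the cheapest dependency-free option.
"""
from __future__ import annotations

import math

import numpy as np

from ..synth import EEGRecording

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int = 8) -> bytes:
    """Format a float into a fixed-width EDF numeric field."""
    for fmt in (f"{value:.6g}", f"{value:.4g}", f"{value:.2g}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise ValueError(f"cannot fit {value} into {width} chars")


def write_edf(path, rec: EEGRecording) -> None:
    """Write a recording as EDF (16-bit, 1 s data records)."""
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError(f"EDF export needs an integer sampling rate, got {fs}")
    fs = int(fs)
    ns = rec.n_channels
    n_records = math.ceil(rec.n_samples / fs)

    data = rec.data
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    # Use the values as actually written in the header so scaling round-trips.
    pmin_w = np.array([float(_num(v).decode()) for v in pmin])
    pmax_w = np.array([float(_num(v).decode()) for v in pmax])
    pmin_w = np.minimum(pmin_w, pmin)
    pmax_w = np.maximum(pmax_w, pmax)

    header_bytes = 256 + 256 * ns
    head = bytearray()
    head += _field("0", 8)
    head += _field("phasestim synthetic subject", 80)
    head += _field("phasestim session", 80)
    head += _field("01.01.00", 8)
    head += _field("00.00.00", 8)
    head += _field(header_bytes, 8)
    head += _field("", 44)
    head += _field(n_records, 8)
    head += _field(1, 8)
    head += _field(ns, 4)
    for lab in rec.channel_labels:
        head += _field(lab, 16)
    head += b"".join(_field("AgAgCl electrode", 80) for _ in range(ns))
    head += b"".join(_field("uV", 8) for _ in range(ns))
    head += b"".join(_num(v) for v in pmin_w)
    head += b"".join(_num(v) for v in pmax_w)
    head += b"".join(_field(_DIG_MIN, 8) for _ in range(ns))
    head += b"".join(_field(_DIG_MAX, 8) for _ in range(ns))
    head += b"".join(_field("", 80) for _ in range(ns))
    head += b"".join(_field(fs, 8) for _ in range(ns))
    head += b"".join(_field("", 32) for _ in range(ns))
    assert len(head) == header_bytes

    padded = np.zeros((ns, n_records * fs))
    padded[:, : rec.n_samples] = data
    scale = (_DIG_MAX - _DIG_MIN) / (pmax_w - pmin_w)
    digital = np.rint((padded - pmin_w[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(head))
        # record-major layout: for each 1 s record, all channels back to back
        records = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)
        fh.write(records.tobytes())


def _parse(raw: bytes, kind=str):
    try:
        text = raw.decode("ascii").strip()
        return kind(text) if text or kind is str else kind(0)
    except (UnicodeDecodeError, ValueError) as exc:
        raise ValueError(f"malformed EDF header field {raw!r}") from exc


def read_edf(path) -> EEGRecording:
    """Read an EDF file written by :func:`write_edf` (or any 16-bit EDF with
    uniform per-signal rates).  The event table is left empty; events travel
    in a delimited sidecar."""
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        header_bytes = _parse(fixed[184:192], int)
        n_records = _parse(fixed[236:244], int)
        record_dur = _parse(fixed[244:252], float)
        ns = _parse(fixed[252:256], int)
        if ns < 1 or record_dur <= 0:
            raise ValueError(f"{path}: bad signal count or record duration")
        sig = fh.read(header_bytes - 256)

        def col(offset: int, width: int, kind):
            base = offset * ns
            return [
                _parse(sig[base + i * width : base + (i + 1) * width], kind)
                for i in range(ns)
            ]

        labels = col(0, 16, str)
        pmin = np.array(col(16 + 80 + 8, 8, float))
        pmax = np.array(col(16 + 80 + 8 + 8, 8, float))
        dmin = np.array(col(16 + 80 + 8 + 16, 8, float))
        dmax = np.array(col(16 + 80 + 8 + 24, 8, float))
        spr = col(16 + 80 + 8 + 32 + 80, 8, int)
        if len(set(spr)) != 1:
            raise ValueError(f"{path}: heterogeneous sampling rates unsupported")
        fs = spr[0] / record_dur

        raw = np.frombuffer(fh.read(), dtype="<i2")
    expected = n_records * ns * spr[0]
    if raw.size < expected:
        raise ValueError(f"{path}: data section truncated "
                         f"({raw.size} of {expected} samples)")
    records = raw[:expected].reshape(n_records, ns, spr[0])
    digital = records.transpose(1, 0, 2).reshape(ns, -1).astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]
    return EEGRecording(data=data, fs=fs, channel_labels=labels, events=[])
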