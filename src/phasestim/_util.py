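"""Small shared numeric helpers (phase wrapping, circular statistics)."""
from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(phi):
    """Wrap angle(s) to the half-open interval [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, TWO_PI) - np.pi


def circular_mean(phi):
    """Circular mean angle of a set of phases."""
    phi = np.asarray(phi, dtype=float)
    return float(np.angle(np.mean(np.exp(1j * phi))))


def circular_abs_error(phi_a, phi_b):
    """Per-sample absolute circular distance between two phase series."""
    return np.abs(wrap_phase(np.asarray(phi_a) - np.asarray(phi_b)))


def next_pow2(n: int) -> int:
    """Smallest power of two >= n."""
    return 1 << max(int(n) - 1, 0).bit_length()
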