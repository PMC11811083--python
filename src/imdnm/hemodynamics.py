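"""Canonical hemodynamic response in the frequency domain.

The kernel is the standard double-gamma difference — a gamma density peaking
at 6 s minus 1/6 of a gamma density peaking at 16 s (unit dispersion).  Both
terms have closed-form Fourier transforms, ``(1 + i*omega*theta)**-k`` for a
gamma density with shape ``k`` and scale ``theta``, so the transfer function
is evaluated analytically and normalized to unit gain at zero frequency.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hrf_transfer", "hrf_kernel"]

_PEAK = 6.0  # response peak (s): gamma shape 6, scale 1
_UNDER = 16.0  # undershoot peak (s): gamma shape 16, scale 1
_RATIO = 1.0 / 6.0  # undershoot amplitude relative to the peak
_DC = 1.0 - _RATIO  # gain at omega = 0 before normalization


def hrf_transfer(freqs_hz) -> np.ndarray:
    """Complex transfer function H(f) of the canonical kernel, H(0) = 1."""
    w = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float)
    z = 1.0 + 1j * w
    return (z**-_PEAK - _RATIO * z**-_UNDER) / _DC


def hrf_kernel(t) -> np.ndarray:
    """Time-domain kernel h(t) (unit-area peak term), for reference/plots."""
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    h = gamma.pdf(t, _PEAK) - _RATIO * gamma.pdf(t, _UNDER)
    return h / _DC
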