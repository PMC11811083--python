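"""Interictal iEEG preprocessing: band-pass, power-line notch, common-average
re-referencing and non-overlapping windowing.

All filters are zero-phase (forward-backward) 4th-order Butterworth designs:
the later per-window regression of each sample on its predecessor is sensitive
to phase lag, which zero-phase filtering avoids.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .data import Recording

__all__ = ["bandpass", "notch", "common_average", "window"]

logger = logging.getLogger(__name__)


def bandpass(rec: Recording, lo: float = 0.5, hi: float = 300.0) -> Recording:
    """Zero-phase Butterworth band-pass between ``lo`` and ``hi`` Hz.

    When ``hi`` reaches the Nyquist frequency (clinical recordings are often
    sampled at 500-600 Hz while the nominal band extends to 300 Hz), it is
    clipped to 0.99 x Nyquist with a logged warning.
    """
    nyq = rec.fs / 2.0
    if lo >= hi:
        raise ValueError(f"band edges out of order: lo={lo} >= hi={hi}")
    if lo <= 0:
        raise ValueError("low edge must be positive")
    if lo >= nyq:
        raise ValueError(f"low edge {lo} Hz is at or above Nyquist ({nyq} Hz)")
    if hi >= nyq:
        hi_clip = 0.99 * nyq
        logger.warning(
            "band upper edge %.1f Hz >= Nyquist %.1f Hz; clipping to %.1f Hz",
            hi, nyq, hi_clip,
        )
        hi = hi_clip
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy_with(signal=sps.sosfiltfilt(sos, rec.signal, axis=1))


def notch(rec: Recording, center: float = 60.0, half_width: float = 2.0) -> Recording:
    """Zero-phase band-stop around ``center`` +/- ``half_width`` Hz."""
    if half_width <= 0:
        raise ValueError("notch half-width must be positive")
    nyq = rec.fs / 2.0
    if center + half_width >= nyq:
        raise ValueError(
            f"notch band {center}+/-{half_width} Hz exceeds Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(
        4, [center - half_width, center + half_width],
        btype="bandstop", fs=rec.fs, output="sos",
    )
    return rec.copy_with(signal=sps.sosfiltfilt(sos, rec.signal, axis=1))


def common_average(rec: Recording) -> Recording:
    """Drop bad channels and re-reference to the common average.

    Bad channels are removed *before* the average so artifacts do not leak
    into the reference.  After re-referencing, the mean across retained
    channels is zero at every sample.
    """
    clean = rec.drop(rec.bad) if rec.bad else rec
    if clean.n_channels < 2:
        raise ValueError(
            "common-average reference needs at least 2 retained channels"
        )
    car = clean.signal - clean.signal.mean(axis=0, keepdims=True)
    return clean.copy_with(signal=car)


def window(
    rec: Recording, win_ms: float = 500.0, stride_ms: float | None = None
) -> list[np.ndarray]:
    """Cut the recording into consecutive windows of ``win_ms`` milliseconds.

    Windows are non-overlapping by default (``stride_ms = win_ms``); the
    trailing remainder shorter than one window is discarded.  A window must
    hold at least ``n_channels + 1`` samples so the per-window least-squares
    transition-matrix fit is identifiable.
    """
    w = int(round(win_ms * rec.fs / 1000.0))
    stride = w if stride_ms is None else int(round(stride_ms * rec.fs / 1000.0))
    if stride <= 0:
        raise ValueError("stride must be positive")
    n_min = rec.n_channels + 1
    if w < n_min:
        min_ms = n_min * 1000.0 / rec.fs
        raise ValueError(
            f"window of {w} samples is too short for {rec.n_channels} "
            f"channels; need at least {n_min} samples ({min_ms:.1f} ms at "
            f"fs={rec.fs:g})"
        )
    starts = range(0, rec.n_samples - w + 1, stride)
    return [rec.signal[:, s : s + w] for s in starts]
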