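"""Source-sink analysis of interictal iEEG.

A linear time-varying dynamic network model is estimated by least squares in
each short window of the multichannel recording,

    x(t+1) = A_j x(t) + e(t),

and the window matrices are summarized by the entrywise mean of their
absolute values, ``A_bar = (1/T) sum_j |A_j|``.  In ``A_bar``, row ``i``
holds the influence every other node exerts on node ``i`` and column ``j``
the influence node ``j`` exerts on the rest of the network.  Channels are
placed in a 2-D rank space (row-rank ``rr``, column-rank ``cr``); sinks —
strongly influenced, weakly influencing — sit near ``(rr, cr) = (1, 1/N)``
and sources near ``(1/N, 1)``.  Four per-channel indices follow:

* sink index ``SI = sqrt(2) - ||(rr, cr) - (1, 1/N)||``,
* source influence ``SF`` — mean inbound weight from the top sources,
* sink connectivity ``SC`` — mean inbound weight from the other top sinks,
* ``ssi`` — the product ``SI * SF * SC`` min-max rescaled to [0, 1] within
  the patient.

High-SSI channels are the hypothesized seizure-onset-zone nodes: sinks that
the surrounding network persistently inhibits between seizures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import Recording
from . import preprocess

__all__ = [
    "DNMResult",
    "estimate_window_A",
    "aggregate_A",
    "source_sink_space",
    "ssi_scores",
    "channel_to_roi",
    "SourceSinkModel",
    "SourceSinkResults",
]

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


@dataclass
class DNMResult:
    """Windowed linear dynamic network model of one recording."""

    A_seq: list  # per-window transition matrices A_j
    A_bar: np.ndarray  # entrywise mean of |A_j|
    residual_var: np.ndarray  # per-window one-step residual variance
    T: int


def estimate_window_A(x: np.ndarray, ridge_rtol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Least-squares one-step transition matrix of one window.

    Minimizes ``sum_t ||x(t+1) - A x(t)||^2``.  A rank-deficient regressor
    block triggers a deterministic ridge fallback with
    ``lambda = 1e-6 * trace(X1 X1') / N``.

    Returns ``(A, residual_variance)``.
    """
    x = np.asarray(x, dtype=float)
    n, w = x.shape
    if w < n + 1:
        raise ValueError(f"window of {w} samples cannot identify a {n}x{n} model")
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples in window")
    x0, x1 = x[:, :-1], x[:, 1:]
    gram = x0 @ x0.T
    s = np.linalg.svd(gram, compute_uv=False)
    if s[0] > 0 and s[-1] / s[0] > ridge_rtol:
        a = np.linalg.solve(gram, x0 @ x1.T).T
    else:
        lam = 1e-6 * np.trace(x1 @ x1.T) / n
        if lam <= 0:
            logger.warning("degenerate (all-zero) window; returning zero matrix")
            return np.zeros((n, n)), 0.0
        logger.warning(
            "rank-deficient window regressors; ridge fallback with lambda=%.3g",
            lam,
        )
        a = np.linalg.solve(gram + lam * np.eye(n), x0 @ x1.T).T
    resid = x1 - a @ x0
    return a, float(np.mean(resid**2))


def aggregate_A(A_seq) -> np.ndarray:
    """Entrywise mean of absolute window matrices (one overall network)."""
    A_seq = list(A_seq)
    if not A_seq:
        raise ValueError("empty window-matrix sequence")
    shape = np.shape(A_seq[0])
    for a in A_seq:
        if np.shape(a) != shape:
            raise ValueError("window matrices differ in shape")
    return np.mean([np.abs(a) for a in A_seq], axis=0)


def source_sink_space(A_bar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-rank and column-rank coordinates of each channel.

    Row strength ``r_i = sum_{j != i} A_bar[i, j]`` (inbound), column
    strength ``c_j = sum_{i != j} A_bar[i, j]`` (outbound).  Both are ranked
    ascending with tie-averaging and scaled by ``1/N`` into ``(0, 1]``.
    """
    A_bar = np.asarray(A_bar, dtype=float)
    n = A_bar.shape[0]
    if A_bar.ndim != 2 or A_bar.shape[1] != n:
        raise ValueError("A_bar must be square")
    if n < 2:
        raise ValueError("source-sink space needs at least 2 channels")
    off = A_bar - np.diag(np.diag(A_bar))
    r = off.sum(axis=1)
    c = off.sum(axis=0)
    rr = rankdata(r) / n
    cr = rankdata(c) / n
    return rr, cr


def _top_set(index: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values (stable order tie-break)."""
    order = np.argsort(-index, kind="stable")
    return order[:k]


def ssi_scores(
    rr: np.ndarray,
    cr: np.ndarray,
    A_bar: np.ndarray,
    q: float = 0.10,
) -> pd.DataFrame:
    """Per-channel sink index, source influence, sink connectivity and SSI.

    ``q`` is the fraction of channels treated as top sources / top sinks
    (``ceil(q * N)`` channels each).  The SSI is min-max rescaled to [0, 1]
    within the recording, so its maximum is 1 barring ties; an all-zero
    network yields all-zero SSI with a warning.
    """
    if not (0 < q <= 0.5):
        raise ValueError(f"top fraction q must be in (0, 0.5], got {q}")
    rr = np.asarray(rr, float)
    cr = np.asarray(cr, float)
    A_bar = np.asarray(A_bar, float)
    n = rr.size
    # distances to the ideal sink (1, 1/N) and ideal source (1/N, 1)
    si = SQRT2 - np.hypot(rr - 1.0, cr - 1.0 / n)
    src = SQRT2 - np.hypot(rr - 1.0 / n, cr - 1.0)
    k = math.ceil(q * n)
    top_sources = _top_set(src, k)
    top_sinks = _top_set(si, k)
    off = A_bar - np.diag(np.diag(A_bar))
    sf = np.empty(n)
    sc = np.empty(n)
    for i in range(n):
        srcs = top_sources[top_sources != i]
        sf[i] = off[i, srcs].mean() if srcs.size else 0.0
        sinks = top_sinks[top_sinks != i]
        sc[i] = off[i, sinks].mean() if sinks.size else 0.0
    raw = si * sf * sc
    span = raw.max() - raw.min()
    if span <= 0:
        logger.warning("flat SSI (all channels tied); scores set to 0")
        ssi = np.zeros(n)
    else:
        ssi = (raw - raw.min()) / span
    df = pd.DataFrame(
        {
            "rr": rr,
            "cr": cr,
            "sink_index": si,
            "source_influence": sf,
            "sink_connectivity": sc,
            "ssi": ssi,
        }
    )
    df["top_source"] = False
    df["top_sink"] = False
    df.loc[top_sources, "top_source"] = True
    df.loc[top_sinks, "top_sink"] = True
    return df


def channel_to_roi(scores: pd.DataFrame, roi_map: dict) -> pd.Series:
    """Average channel SSI within each ROI.

    ``scores`` must be indexed by channel label and carry an ``ssi`` column.
    Channels absent from ``roi_map`` are ignored for ROI scores (but remain
    in the channel table); an ROI with no scored channel is dropped with a
    log message.
    """
    if not roi_map:
        return pd.Series(dtype=float, name="score_ieeg")
    rois = sorted(set(roi_map.values()))
    out = {}
    for roi in rois:
        chans = [c for c, r in roi_map.items() if r == roi and c in scores.index]
        if not chans:
            logger.info("ROI %s has no scored channel; score missing", roi)
            continue
        out[roi] = float(scores.loc[chans, "ssi"].mean())
    return pd.Series(out, name="score_ieeg")


class SourceSinkModel:
    """Source-sink scoring of one interictal iEEG recording.

    Wraps the full chain band-pass -> notch -> common average -> windowing ->
    per-window least squares -> index computation behind a statsmodels-style
    ``fit()``.

    Parameters
    ----------
    recording
        Raw recording (bad channels flagged, not yet dropped).
    window_ms
        Window length for the time-varying model, default 500 ms.
    stride_ms
        Window stride; default equal to ``window_ms`` (non-overlapping).
    band, notch_band
        Band-pass edges in Hz and (center, half-width) of the power-line
        notch.  Either may be ``None`` to skip that filter (synthetic data
        carries no line noise).
    top_frac
        Fraction of channels treated as top sources/sinks.
    car
        Apply the common-average reference (set False for reference-free
        synthetic recordings; bad channels are still dropped).
    """

    def __init__(
        self,
        recording: Recording,
        window_ms: float = 500.0,
        stride_ms: float | None = None,
        band: tuple[float, float] | None = (0.5, 300.0),
        notch_band: tuple[float, float] | None = (60.0, 2.0),
        top_frac: float = 0.10,
        car: bool = True,
    ):
        self.recording = recording
        self.window_ms = window_ms
        self.stride_ms = stride_ms
        self.band = band
        self.notch_band = notch_band
        self.top_frac = top_frac
        self.car = car

    def fit(self) -> "SourceSinkResults":
        rec = self.recording
        if self.band is not None:
            rec = preprocess.bandpass(rec, *self.band)
        if self.notch_band is not None:
            rec = preprocess.notch(rec, *self.notch_band)
        if self.car:
            rec = preprocess.common_average(rec)
        elif rec.bad:
            rec = rec.drop(rec.bad)
        wins = preprocess.window(rec, self.window_ms, self.stride_ms)
        if not wins:
            raise ValueError("recording shorter than one window")
        A_seq, rv = [], []
        for w in wins:
            a, v = estimate_window_A(w)
            A_seq.append(a)
            rv.append(v)
        A_bar = aggregate_A(A_seq)
        dnm = DNMResult(A_seq=A_seq, A_bar=A_bar, residual_var=np.array(rv), T=len(A_seq))
        rr, cr = source_sink_space(A_bar)
        scores = ssi_scores(rr, cr, A_bar, q=self.top_frac)
        scores.index = pd.Index(rec.labels, name="channel")
        return SourceSinkResults(self, rec, dnm, scores)


class SourceSinkResults:
    """Fitted source-sink indices with the underlying dynamic network model."""

    def __init__(
        self,
        model: SourceSinkModel,
        processed: Recording,
        dnm: DNMResult,
        channel_scores: pd.DataFrame,
    ):
        self.model = model
        self.processed = processed
        self.dnm = dnm
        self.channel_scores = channel_scores

    @property
    def A_bar(self) -> np.ndarray:
        return self.dnm.A_bar

    def roi_scores(self) -> pd.Series:
        """Mean SSI per ROI (uses the recording's channel -> ROI map)."""
        return channel_to_roi(self.channel_scores, self.processed.roi_map)

    def summary(self) -> str:
        df = self.channel_scores.sort_values("ssi", ascending=False)
        lines = [
            "Source-sink model",
            "=================",
            f"channels: {self.processed.n_channels}   windows: {self.dnm.T} "
            f"x {self.model.window_ms:g} ms   fs: {self.processed.fs:g} Hz",
            f"mean one-step residual variance: "
            f"{float(np.mean(self.dnm.residual_var)):.4g}",
            "",
            df.to_string(
                float_format=lambda v: f"{v:.3f}",
                columns=[
                    "rr", "cr", "sink_index", "source_influence",
                    "sink_connectivity", "ssi", "top_source", "top_sink",
                ],
            ),
        ]
        return "\n".join(lines)
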