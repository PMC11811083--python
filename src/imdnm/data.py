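"""Core container types and readers for iEEG recordings, ROI series and masks.

The portable fixture format for iEEG is a delimiter-separated channel x sample
matrix accompanied by a JSON sidecar holding the sampling rate, channel labels,
bad-channel list and an optional channel -> ROI map.  Clinical EDF files are
read through :mod:`mne`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "RoiSeries",
    "RoiMask",
    "read_recording",
    "write_recording",
    "read_roi_series",
]


@dataclass
class Recording:
    """A multichannel iEEG recording.

    Parameters
    ----------
    signal
        Channel x sample matrix in microvolts.
    fs
        Sampling rate in samples/second.
    labels
        Unique channel names, one per row of ``signal``.
    bad
        Labels of channels flagged bad by clinical review (a subset of
        ``labels``); they are retained until preprocessing drops them.
    roi_map
        Partial map from channel label to ROI id.  Channels absent from the
        map carry no ROI and are still scored at the channel level.
    """

    signal: np.ndarray
    fs: float
    labels: list[str]
    bad: set[str] = field(default_factory=set)
    roi_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channel x sample matrix")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.signal.shape[0]:
            raise ValueError(
                f"label count ({len(self.labels)}) does not match number of "
                f"signal rows ({self.signal.shape[0]})"
            )
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels: {dup}")
        self.bad = set(self.bad)
        unknown = self.bad - set(self.labels)
        if unknown:
            raise ValueError(f"bad channels not among labels: {sorted(unknown)}")
        bad_ix = ~np.isfinite(self.signal)
        if bad_ix.any():
            ch, samp = map(int, np.argwhere(bad_ix)[0])
            raise ValueError(
                f"non-finite sample at channel {self.labels[ch]!r} "
                f"(row {ch}), sample {samp}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, signal: np.ndarray | None = None, **kw) -> "Recording":
        return Recording(
            signal=self.signal if signal is None else signal,
            fs=kw.get("fs", self.fs),
            labels=kw.get("labels", list(self.labels)),
            bad=kw.get("bad", set(self.bad)),
            roi_map=kw.get("roi_map", dict(self.roi_map)),
        )

    def drop(self, labels: set[str]) -> "Recording":
        """Return a copy without the given channels."""
        keep = [i for i, l in enumerate(self.labels) if l not in labels]
        if not keep:
            raise ValueError("dropping all channels leaves an empty recording")
        kept = [self.labels[i] for i in keep]
        return Recording(
            signal=self.signal[keep],
            fs=self.fs,
            labels=kept,
            bad=self.bad & set(kept),
            roi_map={l: r for l, r in self.roi_map.items() if l in kept},
        )


@dataclass
class RoiSeries:
    """ROI x volume BOLD series with its repetition time.

    ``provenance`` records how the series were obtained: ``"eigenvariate"``
    (first-eigenvariate summaries of voxel sets), ``"mean"`` (unweighted
    voxel means) or ``"synthetic"``.
    """

    series: np.ndarray
    tr: float
    roi_ids: list[str]
    provenance: str = "eigenvariate"

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be a 2-D ROI x volume matrix")
        if self.tr <= 0:
            raise ValueError(f"repetition time must be positive, got {self.tr}")
        self.roi_ids = [str(r) for r in self.roi_ids]
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("ROI ids must be unique")
        if len(self.roi_ids) != self.series.shape[0]:
            raise ValueError("roi_ids length must match series rows")
        if self.series.shape[0] < 2:
            raise ValueError("a connectivity model needs at least 2 ROIs")
        if self.provenance not in ("eigenvariate", "mean", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not np.isfinite(self.series).all():
            raise ValueError("non-finite values in ROI series")

    @property
    def n_rois(self) -> int:
        return self.series.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.series.shape[1]


@dataclass
class RoiMask:
    """A set of 0-based flat voxel indices on an explicit grid."""

    voxels: frozenset
    roi_id: str
    grid_shape: tuple

    def __post_init__(self) -> None:
        self.voxels = frozenset(int(v) for v in self.voxels)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if not self.voxels:
            raise ValueError(f"ROI mask {self.roi_id!r} is empty")
        n = int(np.prod(self.grid_shape))
        if min(self.voxels) < 0 or max(self.voxels) >= n:
            raise ValueError(
                f"voxel indices of ROI {self.roi_id!r} fall outside the grid "
                f"of {n} voxels"
            )

    def __len__(self) -> int:
        return len(self.voxels)

    def overlap(self, other: "RoiMask") -> float:
        """|intersection| / |smaller mask|; requires a common grid."""
        if self.grid_shape != other.grid_shape:
            raise ValueError("masks live on different grids")
        inter = len(self.voxels & other.voxels)
        return inter / min(len(self), len(other))

    def fraction_inside(self, other: "RoiMask") -> float:
        """Fraction of this mask's voxels contained in ``other``."""
        if self.grid_shape != other.grid_shape:
            raise ValueError("masks live on different grids")
        return len(self.voxels & other.voxels) / len(self)


def _read_sidecar(sidecar: str | Path) -> dict:
    with open(sidecar) as fh:
        meta = json.load(fh)
    return meta


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> Recording:
    """Load a recording from an EDF file or a delimited matrix + JSON sidecar.

    The sidecar supplies ``fs`` and ``labels`` for the matrix format (where
    the file itself carries none) and may add ``bad`` and ``roi_map`` for
    either format.
    """
    path = Path(path)
    meta = _read_sidecar(sidecar) if sidecar is not None else {}
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        if len(set(labels)) != len(labels):
            raise ValueError("EDF carries duplicate channel labels")
        signal = raw.get_data() * 1e6  # volts -> microvolts
        fs = float(raw.info["sfreq"])
    else:
        signal = np.loadtxt(path, delimiter=meta.get("delimiter", ","), ndmin=2)
        if "fs" not in meta or "labels" not in meta:
            raise ValueError(
                "delimited recordings need a sidecar with 'fs' and 'labels'"
            )
        fs = float(meta["fs"])
        labels = list(meta["labels"])
    return Recording(
        signal=signal,
        fs=meta.get("fs", fs),
        labels=labels,
        bad=set(meta.get("bad", [])),
        roi_map=dict(meta.get("roi_map", {})),
    )


def write_recording(rec: Recording, path: str | Path, sidecar: str | Path) -> None:
    """Write the delimited matrix + sidecar representation of a recording."""
    np.savetxt(path, rec.signal, delimiter=",", fmt="%.17g")
    meta = {
        "fs": rec.fs,
        "labels": list(rec.labels),
        "bad": sorted(rec.bad),
        "roi_map": dict(rec.roi_map),
        "delimiter": ",",
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_roi_series(path: str | Path, tr: float, provenance: str = "eigenvariate") -> RoiSeries:
    """Read an ROI x volume table (TSV/CSV with ROI ids in the first column)."""
    import pandas as pd

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return RoiSeries(
        series=df.to_numpy(dtype=float),
        tr=tr,
        roi_ids=[str(i) for i in df.index],
        provenance=provenance,
    )
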