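"""Synthetic data with planted ground truth.

Three generators cover the full pipeline without any clinical data:

* :func:`simulate_ieeg` — a stable linear network iterated at iEEG rates,
  with designated *sink* channels that receive strong influence and project
  little (the interictal signature hypothesized for the seizure onset zone).
* :func:`simulate_bold` — a linear stochastic system over ROIs driven by
  power-law fluctuations, observed through the canonical hemodynamic
  transfer function with measurement noise, sampled at the repetition time.
  One ROI is planted with dominant excitatory outbound connectivity.
* :func:`simulate_cohort` — a full surgical cohort: per-patient recordings,
  ROI series, voxel masks and an outcome plan in which good-outcome patients
  had their planted seizure-onset region resected and poor-outcome patients
  had the resection displaced onto other regions.

All generators are deterministic under their seed and emit their ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Recording, RoiMask, RoiSeries
from .cohort import PatientRecord
from .csd import CSDParams, forward_csd

__all__ = [
    "GroundTruth",
    "simulate_ieeg",
    "simulate_bold",
    "simulate_cohort",
    "CohortSim",
    "PatientSim",
]

# Planted effect sizes: the documented operating point of the synthetic
# study conditions.
SINK_INBOUND = 0.4  # gain into a planted sink channel
SINK_OUTBOUND = 0.05  # gain out of a planted sink channel
BACKGROUND = 0.1  # background coupling magnitude
SPECTRAL_RADIUS = 0.95  # discrete-time stability rescale target

FMRI_OUTBOUND = 0.4  # planted excitatory outbound weight (1/s)
FMRI_BACKGROUND = 0.1  # background coupling magnitude (1/s), random sign
FMRI_DIAG = -0.5  # fixed self-decay (1/s)
FMRI_ALPHA = 1.0  # endogenous fluctuation amplitude
FMRI_BETA = 1.0  # endogenous power-law slope
FMRI_NOISE_ALPHA = 0.5  # observation-noise amplitude
FMRI_NOISE_BETA = 1.0  # observation-noise slope

MICROVOLT_SCALE = 50.0


@dataclass
class GroundTruth:
    """Planted structure emitted next to every synthetic dataset."""

    true_A_ieeg: np.ndarray | None = None
    true_A_fmri: np.ndarray | None = None
    soz_channels: list = field(default_factory=list)
    soz_rois: list = field(default_factory=list)
    outcome_plan: dict = field(default_factory=dict)


def _planted_ieeg_A(n_channels: int, sinks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stable transition matrix with planted sink rows/columns.

    Entry magnitudes are jittered by a U(0.75, 1.25) factor so rank
    statistics are not degenerate; the matrix is rescaled to the target
    spectral radius, which preserves all rank structure.
    """
    u = rng.uniform(0.75, 1.25, size=(n_channels, n_channels))
    a = BACKGROUND * u
    a[sinks, :] = SINK_INBOUND * u[sinks, :]  # strong inbound (rows)
    a[:, sinks] = SINK_OUTBOUND * u[:, sinks]  # weak outbound (columns)
    signs = rng.choice([-1.0, 1.0], size=a.shape)
    a = a * signs
    np.fill_diagonal(a, 0.5 * rng.uniform(0.75, 1.25, size=n_channels))
    rho = np.max(np.abs(np.linalg.eigvals(a)))
    return a * (SPECTRAL_RADIUS / rho)


def simulate_ieeg(
    n_channels: int = 20,
    n_soz: int = 2,
    duration_s: float = 30.0,
    fs: float = 500.0,
    snr: float = 4.0,
    seed: int = 0,
    n_regimes: int = 1,
) -> tuple[Recording, GroundTruth]:
    """Simulate an interictal recording from a planted linear network.

    The network ``x(t+1) = A x(t) + e(t)`` is driven by unit white noise;
    ``snr`` is the ratio of signal variance to added measurement-noise
    variance.  With ``snr = inf`` both noises are switched off and the
    system relaxes from a random initial state, so the transition matrix is
    recoverable to numerical precision.  ``n_regimes > 1`` re-draws the
    background couplings piecewise to emulate a time-varying network (the
    planted sink structure is kept in every regime).
    """
    if not 0 < n_soz < n_channels / 2:
        raise ValueError("need 0 < n_soz < n_channels / 2")
    if fs < 200:
        raise ValueError("sampling rate below 200 Hz is not supported")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    sinks = np.sort(rng.choice(n_channels, size=n_soz, replace=False))
    n_samples = int(round(duration_s * fs))
    noise_free = np.isinf(snr)
    x = np.empty((n_channels, n_samples))
    bounds = np.linspace(0, n_samples, n_regimes + 1).astype(int)
    A_first = None
    state = rng.standard_normal(n_channels) if noise_free else np.zeros(n_channels)
    for r in range(n_regimes):
        A = _planted_ieeg_A(n_channels, sinks, rng)
        if A_first is None:
            A_first = A
        for t in range(bounds[r], bounds[r + 1]):
            e = 0.0 if noise_free else rng.standard_normal(n_channels)
            state = A @ state + e
            x[:, t] = state
    signal = MICROVOLT_SCALE * x
    if not noise_free:
        noise_sd = signal.std() / np.sqrt(snr)
        signal = signal + noise_sd * rng.standard_normal(signal.shape)
    labels = [f"CH{i + 1:02d}" for i in range(n_channels)]
    rec = Recording(signal=signal, fs=fs, labels=labels)
    gt = GroundTruth(
        true_A_ieeg=A_first,
        soz_channels=[labels[i] for i in sinks],
    )
    return rec, gt


def _planted_bold_A(
    n_rois: int, soz: int, rng: np.random.Generator
) -> np.ndarray:
    """Stable signed connectivity with one dominant excitatory-outbound ROI."""
    a = FMRI_BACKGROUND * rng.uniform(0.75, 1.25, size=(n_rois, n_rois))
    a *= rng.choice([-1.0, 1.0], size=a.shape)
    a[:, soz] = FMRI_OUTBOUND * rng.uniform(0.75, 1.25, size=n_rois)
    np.fill_diagonal(a, FMRI_DIAG)
    # enforce continuous-time stability with margin, shrinking couplings if needed
    for _ in range(64):
        if np.max(np.linalg.eigvals(a).real) < -0.05:
            break
        off = a - np.diag(np.diag(a))
        a = 0.9 * off
        np.fill_diagonal(a, FMRI_DIAG)
    return a


def simulate_bold(
    n_rois: int = 3,
    soz_roi: int = 0,
    n_volumes: int = 600,
    tr: float = 2.0,
    seed: int = 0,
    use_hrf: bool = True,
    f_floor: float = 1.0 / 128.0,
) -> tuple[RoiSeries, GroundTruth]:
    """Simulate hemodynamically filtered ROI series with a planted driver.

    The series are synthesized in the frequency domain: at each FFT
    frequency the model cross-spectrum (endogenous power-law fluctuations
    shaped by the connectivity resolvent and the hemodynamic transfer
    function, plus observation noise) is factorized and used to draw a
    complex Gaussian coefficient, and the inverse FFT returns a real series
    whose spectrum matches the generative model by construction.

    Below ``f_floor`` (Hz) the power-law spectra are held at their
    ``f_floor`` value: acquisition pipelines high-pass resting-state data
    (cutoff on the order of 100 s), so unbounded ultra-slow power is not a
    feature of analyzable recordings.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    if not 0 <= soz_roi < n_rois:
        raise ValueError("soz_roi out of range")
    if n_volumes < 128:
        raise ValueError("need at least 128 volumes")
    rng = np.random.default_rng(seed)
    A = _planted_bold_A(n_rois, soz_roi, rng)
    params = CSDParams(
        A=A,
        alpha_v=np.full(n_rois, FMRI_ALPHA),
        beta_v=np.full(n_rois, FMRI_BETA),
        alpha_e=FMRI_NOISE_ALPHA,
        beta_e=FMRI_NOISE_BETA,
    )
    n = n_volumes
    freqs = np.fft.rfftfreq(n, d=tr)[1:]  # positive frequencies
    S = forward_csd(params, np.maximum(freqs, f_floor), use_hrf=use_hrf)
    Y = np.zeros((n_rois, n // 2 + 1), dtype=complex)
    scale = np.sqrt(n / tr)
    for k in range(freqs.size):
        # Hermitian PSD factor; tiny jitter guards the Cholesky
        L = np.linalg.cholesky(S[k] + 1e-12 * np.eye(n_rois))
        xi = (rng.standard_normal(n_rois) + 1j * rng.standard_normal(n_rois)) / np.sqrt(2)
        Y[:, k + 1] = scale * (L @ xi)
    series = np.fft.irfft(Y, n=n, axis=1)
    roi_ids = [f"R{i + 1}" for i in range(n_rois)]
    data = RoiSeries(series=series, tr=tr, roi_ids=roi_ids, provenance="synthetic")
    gt = GroundTruth(true_A_fmri=A, soz_rois=[roi_ids[soz_roi]])
    return data, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class PatientSim:
    """All synthetic data of one cohort patient."""

    record: PatientRecord
    recording: Recording
    roi_series: RoiSeries
    roi_masks: dict  # roi_id -> RoiMask
    resection: RoiMask
    plan_rois: list  # surgically evaluated/targeted regions
    soz_roi: str
    truth: GroundTruth


@dataclass
class CohortSim:
    """A synthetic surgical cohort with planted outcomes."""

    patients: list
    seed: int

    def records(self) -> list:
        return [p.record for p in self.patients]


# mirrors the reference study's mix of 2-, 3- and 4-region candidate sets
_ROI_COUNT_CHOICES = (2, 3, 4)
_ROI_COUNT_WEIGHTS = (1 / 16, 7 / 16, 8 / 16)
_ENGEL_GOOD = ("I", "II")
_ENGEL_GOOD_P = (2 / 3, 1 / 3)
_ENGEL_POOR = ("III", "IV")
_ENGEL_POOR_P = (1 / 5, 4 / 5)

COHORT_GRID = (15, 15, 6)
CHANNELS_PER_ROI = 3
EXTRA_CHANNELS = 2  # implanted contacts outside any candidate region
COHORT_IEEG_SECONDS = 12.0
COHORT_IEEG_FS = 250.0
COHORT_IEEG_SNR = 0.65
COHORT_BOLD_VOLUMES = 220


def _block_mask(roi_id: str, block: int, grid: tuple) -> RoiMask:
    """Disjoint 3x3x3 cube for block index ``block`` on the cohort grid."""
    nx, ny, nz = grid
    bx, by = nx // 3, ny // 3
    ix, iy = block % bx, (block // bx) % by
    iz = block // (bx * by)
    vox = []
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                vox.append(
                    np.ravel_multi_index(
                        (3 * ix + dx, 3 * iy + dy, 3 * iz + dz), grid
                    )
                )
    return RoiMask(voxels=frozenset(int(v) for v in vox), roi_id=roi_id, grid_shape=grid)


def simulate_cohort(
    n_patients: int = 17,
    frac_good: float = 12 / 17,
    seed: int = 0,
) -> CohortSim:
    """Build a full synthetic cohort with planted outcome structure.

    Good-outcome patients (fraction ``frac_good``, rounded to the nearest
    count) have their planted seizure-onset region among the surgically
    targeted regions and covered by the resection mask; poor-outcome
    patients have the resection displaced onto non-onset regions (empty
    intersection with the planted region).
    """
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    if not 0 < frac_good < 1:
        raise ValueError("frac_good must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_good = int(round(frac_good * n_patients))
    n_good = min(max(n_good, 1), n_patients - 1)
    good_flags = np.array([True] * n_good + [False] * (n_patients - n_good))
    rng.shuffle(good_flags)
    patients = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        good = bool(good_flags[p])
        n_rois = int(rng.choice(_ROI_COUNT_CHOICES, p=_ROI_COUNT_WEIGHTS))
        roi_ids = [f"{pid}-R{r + 1}" for r in range(n_rois)]
        soz_ix = int(rng.integers(n_rois))
        soz_roi = roi_ids[soz_ix]

        # iEEG: channels grouped by ROI plus a couple of unmapped contacts;
        # sinks are the onset ROI's channels
        n_channels = CHANNELS_PER_ROI * n_rois + EXTRA_CHANNELS
        rec, gt_ieeg = simulate_ieeg(
            n_channels=n_channels,
            n_soz=CHANNELS_PER_ROI,
            duration_s=COHORT_IEEG_SECONDS,
            fs=COHORT_IEEG_FS,
            snr=COHORT_IEEG_SNR,
            seed=int(rng.integers(2**31 - 1)),
        )
        # map channels to ROIs so the sink channels land on the onset ROI
        sink_labels = list(gt_ieeg.soz_channels)
        other_labels = [l for l in rec.labels if l not in sink_labels]
        roi_map = {}
        for lab in sink_labels:
            roi_map[lab] = soz_roi
        k = 0
        for r, roi in enumerate(roi_ids):
            if roi == soz_roi:
                continue
            for _ in range(CHANNELS_PER_ROI):
                roi_map[other_labels[k]] = roi
                k += 1
        rec = rec.copy_with(roi_map=roi_map)

        series, gt_bold = simulate_bold(
            n_rois=n_rois,
            soz_roi=soz_ix,
            n_volumes=COHORT_BOLD_VOLUMES,
            seed=int(rng.integers(2**31 - 1)),
        )
        series = RoiSeries(
            series=series.series, tr=series.tr, roi_ids=roi_ids,
            provenance="synthetic",
        )

        blocks = rng.choice(
            (COHORT_GRID[0] // 3) * (COHORT_GRID[1] // 3) * (COHORT_GRID[2] // 3),
            size=n_rois, replace=False,
        )
        roi_masks = {
            roi: _block_mask(roi, int(b), COHORT_GRID)
            for roi, b in zip(roi_ids, blocks)
        }
        non_soz = [r for r in roi_ids if r != soz_roi]
        if good:
            extra = [str(rng.choice(non_soz))] if non_soz else []
            plan = [soz_roi] + extra
        else:
            n_plan = min(2, len(non_soz))
            plan = [str(r) for r in rng.choice(non_soz, size=n_plan, replace=False)]
        res_vox = frozenset().union(*(roi_masks[r].voxels for r in plan))
        resection = RoiMask(voxels=res_vox, roi_id=f"{pid}-resection", grid_shape=COHORT_GRID)

        engel = (
            str(rng.choice(_ENGEL_GOOD, p=_ENGEL_GOOD_P))
            if good
            else str(rng.choice(_ENGEL_POOR, p=_ENGEL_POOR_P))
        )
        record = PatientRecord(
            id=pid,
            sex=int(rng.random() < 9 / 17),
            age=float(rng.integers(3, 16)),
            exclusion=None,
            procedure=int(rng.choice([1, 2])),
            lobe=int(rng.choice([1, 2, 3, 4, 5])),
            side=int(rng.choice([0, 1])),
            etiology=int(rng.choice([1, 2, 3, 4, 5, 6, 7])),
            engel_raw=engel,
            engel_class=engel,
        )
        truth = GroundTruth(
            true_A_ieeg=gt_ieeg.true_A_ieeg,
            true_A_fmri=gt_bold.true_A_fmri,
            soz_channels=gt_ieeg.soz_channels,
            soz_rois=[soz_roi],
            outcome_plan={"resection_covers_soz": good},
        )
        patients.append(
            PatientSim(
                record=record,
                recording=rec,
                roi_series=series,
                roi_masks=roi_masks,
                resection=resection,
                plan_rois=plan,
                soz_roi=soz_roi,
                truth=truth,
            )
        )
    return CohortSim(patients=patients, seed=seed)
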