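"""Cross-spectral effective connectivity of resting-state ROI series.

The generative model is a linear stochastic system over ROIs,

    dz/dt = A z + v(t),      y = h * z + e,

where ``A`` (1/s) is signed effective connectivity with the diagonal fixed
at a stable self-decay, ``v`` are endogenous fluctuations with power-law
spectra ``g_v(w) = diag(alpha_v * w**-beta_v)``, ``e`` is observation noise
with spectrum ``g_e(w) = diag(alpha_e * w**-beta_e)`` and ``h`` the canonical
hemodynamic kernel.  The predicted cross-spectral density is

    g_y(w) = H(w) K(w) g_v(w) K(w)^H H(w)* + g_e(w),   K(w) = (i w I - A)^-1.

Fitting proceeds in two steps: a multivariate autoregression of the ROI
series yields an empirical CSD on a log-spaced frequency grid, and the model
parameters are then estimated by Gauss-Newton ascent on the Laplace
(free-energy) approximation to log model evidence under Gaussian priors.
Bayesian model reduction scores every on/off pattern of connections in
closed form from the full posterior, and Bayesian model averaging weights
the best patterns by evidence.  An ROI's final score is its positive
(excitatory) outbound connectivity, min-max normalized within the subject —
the hypothesized seizure-onset zone is the region that dominates in
excitatory outbound coupling.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RoiMask, RoiSeries
from .hemodynamics import hrf_transfer

__all__ = [
    "CSDParams",
    "CSDPriors",
    "forward_csd",
    "mvar_csd",
    "eigenvariate",
    "merge_rois",
    "CrossSpectralModel",
    "CrossSpectralResults",
    "ModelSpace",
    "bayesian_model_reduction",
    "bayesian_model_average",
    "outbound_excitation_score",
    "default_freqs",
]

logger = logging.getLogger(__name__)

DIAG_DEFAULT = -0.5  # fixed self-decay (1/s); not estimated
REDUCED_PRIOR_VAR = 1e-8  # prior variance of a switched-off connection
STABILITY_MARGIN = 1e-6


def default_freqs(n: int = 16, lo: float = 1.0 / 128.0, hi: float = 0.25) -> np.ndarray:
    """Log-spaced frequency grid (Hz) for spectral fitting.

    16 points keep adjacent grid points approximately independent given the
    spectral smoothing of the autoregressive estimator; the upper bound is
    deliberately above the conventional 0.1 Hz resting-state cutoff.
    """
    return np.geomspace(lo, hi, n)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


@dataclass
class CSDParams:
    """Parameters of the cross-spectral generative model."""

    A: np.ndarray  # n x n, 1/s; diagonal is the fixed self-decay
    alpha_v: np.ndarray  # per-ROI fluctuation amplitude (> 0)
    beta_v: np.ndarray  # per-ROI power-law slope (> 0)
    alpha_e: float  # observation-noise amplitude (> 0)
    beta_e: float  # observation-noise slope (> 0)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = self.A.shape[0]
        self.alpha_v = np.broadcast_to(np.asarray(self.alpha_v, float), (n,)).copy()
        self.beta_v = np.broadcast_to(np.asarray(self.beta_v, float), (n,)).copy()

    @property
    def n_rois(self) -> int:
        return self.A.shape[0]

    def is_stable(self, margin: float = STABILITY_MARGIN) -> bool:
        return bool(np.max(np.linalg.eigvals(self.A).real) < -margin)


def forward_csd(params: CSDParams, freqs, use_hrf: bool = True) -> np.ndarray:
    """Predicted cross-spectral density g_y at each frequency (Hz).

    Returns a complex array of shape ``(n_freqs, n, n)``; every slice is
    Hermitian positive semidefinite.  Raises ``ValueError`` for an unstable
    connectivity matrix.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if not params.is_stable():
        raise ValueError("unstable connectivity matrix; refusing to evaluate")
    n = params.n_rois
    eye = np.eye(n)
    h = hrf_transfer(freqs) if use_hrf else np.ones_like(freqs, dtype=complex)
    w = 2.0 * np.pi * freqs
    out = np.empty((freqs.size, n, n), dtype=complex)
    for k in range(freqs.size):
        K = np.linalg.inv(1j * w[k] * eye - params.A)
        gv = params.alpha_v * w[k] ** (-params.beta_v)
        ge = params.alpha_e * w[k] ** (-params.beta_e)
        S = (abs(h[k]) ** 2) * (K * gv) @ K.conj().T + ge * eye
        out[k] = 0.5 * (S + S.conj().T)
    return out


# ---------------------------------------------------------------------------
# empirical CSD via multivariate autoregression
# ---------------------------------------------------------------------------


def mvar_fit(series: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares VAR(p) fit of an ROI x volume matrix (demeaned).

    Returns ``(coefs, sigma)`` with ``coefs`` of shape ``(p, n, n)`` and the
    residual covariance ``sigma``.
    """
    y = np.asarray(series, dtype=float)
    n, t = y.shape
    if t <= order * n + order:
        raise ValueError(
            f"{t} volumes are too few for a VAR({order}) over {n} ROIs"
        )
    y = y - y.mean(axis=1, keepdims=True)
    # target: y[:, p:]; regressors: stacked lags
    X = np.vstack([y[:, order - k - 1 : t - k - 1] for k in range(order)])
    Y = y[:, order:]
    B, *_ = np.linalg.lstsq(X.T, Y.T, rcond=None)
    B = B.T  # n x (n*p)
    resid = Y - B @ X
    sigma = resid @ resid.T / (Y.shape[1] - n * order)
    coefs = B.reshape(n, order, n).transpose(1, 0, 2)
    return coefs, sigma


def mvar_csd(
    data: RoiSeries, freqs, order: int = 8
) -> np.ndarray:
    """Empirical cross-spectral density (per-Hz, two-sided) from a VAR fit.

    ``S(f) = tr * Phi(f)^-1 Sigma Phi(f)^-H`` with
    ``Phi(f) = I - sum_k A_k exp(-2 pi i f k tr)``.
    """
    coefs, sigma = mvar_fit(data.series, order)
    freqs = np.asarray(freqs, dtype=float)
    n = data.n_rois
    eye = np.eye(n)
    out = np.empty((freqs.size, n, n), dtype=complex)
    for k, f in enumerate(freqs):
        phi = eye.astype(complex).copy()
        for lag in range(coefs.shape[0]):
            phi -= coefs[lag] * np.exp(-2j * np.pi * f * (lag + 1) * data.tr)
        pinv = np.linalg.inv(phi)
        S = data.tr * pinv @ sigma @ pinv.conj().T
        out[k] = 0.5 * (S + S.conj().T)
    return out


def welch_csd(data: RoiSeries, nperseg: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Windowed-periodogram (Welch) CSD matrix at the Welch frequency grid.

    Returns ``(freqs, S)`` with ``S`` two-sided per-Hz, shape
    ``(n_freqs, n, n)``; the zero-frequency bin is dropped.
    """
    from scipy.signal import csd as _csd

    y = data.series - data.series.mean(axis=1, keepdims=True)
    n = data.n_rois
    fs = 1.0 / data.tr
    freqs = None
    out = None
    for i in range(n):
        for j in range(n):
            f, s = _csd(
                y[i], y[j], fs=fs, nperseg=min(nperseg, y.shape[1]),
                return_onesided=False, scaling="density",
            )
            keep = f > 0
            if out is None:
                freqs = f[keep]
                out = np.empty((freqs.size, n, n), dtype=complex)
            # scipy's Pxy is conj(X) * Y; this package uses S_ij = <Y_i Y_j*>
            out[:, i, j] = np.conj(s[keep])
    order = np.argsort(freqs)
    return freqs[order], out[order]


# ---------------------------------------------------------------------------
# ROI summaries
# ---------------------------------------------------------------------------


def eigenvariate(voxels: np.ndarray, stat: np.ndarray, thresh: float) -> np.ndarray:
    """First-eigenvariate summary of the voxels passing a significance cut.

    ``voxels`` is voxel x volume; a voxel enters when ``stat < thresh``.  The
    summary is the first right singular vector of the demeaned passing block,
    sign-aligned with the mean passing-voxel series and scaled to unit
    variance.
    """
    voxels = np.asarray(voxels, dtype=float)
    stat = np.asarray(stat, dtype=float)
    keep = stat < thresh
    if not keep.any():
        raise ValueError(
            f"no voxel passes the significance threshold {thresh}; "
            "consider a looser threshold"
        )
    block = voxels[keep]
    block = block - block.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(block, full_matrices=False)
    series = vt[0]
    mean_series = block.mean(axis=0)
    if np.dot(series, mean_series) < 0:
        series = -series
    sd = series.std()
    if sd > 0:
        series = series / sd
    return series


def merge_rois(masks: list[RoiMask], overlap_frac: float = 0.8) -> list[RoiMask]:
    """Union masks whose pairwise overlap exceeds ``overlap_frac``.

    Overlap is ``|intersection| / |smaller mask|`` and merging is transitive
    (connected components of the overlap graph).  Merged masks concatenate
    their ROI ids with ``+``.
    """
    if not masks:
        return []
    grid = masks[0].grid_shape
    for m in masks:
        if m.grid_shape != grid:
            raise ValueError("masks live on different grids")
    parent = list(range(len(masks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(masks)), 2):
        if masks[i].overlap(masks[j]) > overlap_frac:
            parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(masks)):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(masks[members[0]])
        else:
            vox = frozenset().union(*(masks[i].voxels for i in members))
            rid = "+".join(masks[i].roi_id for i in members)
            merged.append(RoiMask(voxels=vox, roi_id=rid, grid_shape=grid))
    return merged


# ---------------------------------------------------------------------------
# parameter packing and priors
# ---------------------------------------------------------------------------


def _off_indices(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(n) if i != j]


@dataclass
class CSDPriors:
    """Gaussian priors over the free parameters.

    Off-diagonal connectivity is in natural signed units (an excitatory or
    inhibitory rate cannot live on a log scale); amplitudes and slopes are
    log-parameterized to keep them positive.
    """

    var_a: float = 1.0 / 64.0  # off-diagonal A
    var_log_alpha: float = 1.0 / 16.0
    var_log_beta: float = 1.0 / 16.0
    diag: float = DIAG_DEFAULT  # fixed, not estimated

    def pack(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Prior mean and variance vectors for ``n`` ROIs."""
        k_a = n * (n - 1)
        mean = np.zeros(k_a + 2 * n + 2)
        var = np.concatenate(
            [
                np.full(k_a, self.var_a),
                np.full(n, self.var_log_alpha),
                np.full(n, self.var_log_beta),
                [self.var_log_alpha, self.var_log_beta],
            ]
        )
        return mean, var


def _unpack(theta: np.ndarray, n: int, diag: float) -> CSDParams:
    k_a = n * (n - 1)
    A = np.full((n, n), 0.0)
    for k, (i, j) in enumerate(_off_indices(n)):
        A[i, j] = theta[k]
    np.fill_diagonal(A, diag)
    alpha_v = np.exp(theta[k_a : k_a + n])
    beta_v = np.exp(theta[k_a + n : k_a + 2 * n])
    alpha_e = float(np.exp(theta[k_a + 2 * n]))
    beta_e = float(np.exp(theta[k_a + 2 * n + 1]))
    return CSDParams(A=A, alpha_v=alpha_v, beta_v=beta_v, alpha_e=alpha_e, beta_e=beta_e)


def _features(csd: np.ndarray) -> np.ndarray:
    """Real feature vector of a stack of Hermitian matrices.

    Diagonal (real) entries plus real and imaginary parts of the upper
    triangle, concatenated over frequencies.
    """
    nf, n, _ = csd.shape
    iu = np.triu_indices(n, k=1)
    parts = [csd[:, np.arange(n), np.arange(n)].real]
    if iu[0].size:
        parts.append(csd[:, iu[0], iu[1]].real)
        parts.append(csd[:, iu[0], iu[1]].imag)
    return np.concatenate([p.ravel() for p in parts])


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


class CrossSpectralModel:
    """Cross-spectral effective-connectivity model of one ROI series.

    Parameters
    ----------
    data
        ROI x volume series with its repetition time (2 to 8 ROIs).
    freqs
        Frequency grid in Hz; default 32 log-spaced points in [1/128, 0.25].
    mvar_order
        Order of the autoregression used for the empirical CSD.
    priors
        Gaussian priors over free parameters (:class:`CSDPriors`).
    use_hrf
        Include the canonical hemodynamic transfer function (set False for
        directly observed neural series in unit tests).
    """

    def __init__(
        self,
        data: RoiSeries,
        freqs: np.ndarray | None = None,
        mvar_order: int = 8,
        priors: CSDPriors | None = None,
        use_hrf: bool = True,
    ):
        if data.n_rois < 2:
            raise ValueError("connectivity is undefined for a single ROI")
        if data.n_rois > 8:
            raise ValueError("model is limited to 8 ROIs")
        if data.n_volumes < 8 * data.n_rois:
            raise ValueError(
                f"{data.n_volumes} volumes are too few for {data.n_rois} ROIs"
            )
        self.data = data
        self.freqs = default_freqs() if freqs is None else np.asarray(freqs, float)
        self.mvar_order = mvar_order
        self.priors = priors or CSDPriors()
        self.use_hrf = use_hrf
        self.n = data.n_rois
        self._prepare()

    def _prepare(self) -> None:
        emp = mvar_csd(self.data, self.freqs, order=self.mvar_order)
        # Whiten per frequency by the mean auto-spectrum so every band
        # contributes comparably despite the power-law fall-off.
        self._weights = 1.0 / np.maximum(
            emp[:, np.arange(self.n), np.arange(self.n)].real.mean(axis=1), 1e-300
        )
        # Rescale the data spectrum so the zero-parameter model (alpha = 1)
        # predicts the observed overall power; BOLD units are arbitrary and
        # this keeps the tight log-amplitude priors centered sensibly.
        theta0 = np.zeros(self.n * (self.n - 1) + 2 * self.n + 2)
        m0 = forward_csd(
            _unpack(theta0, self.n, self.priors.diag), self.freqs, self.use_hrf
        )
        num = emp[:, np.arange(self.n), np.arange(self.n)].real.mean()
        den = m0[:, np.arange(self.n), np.arange(self.n)].real.mean()
        self._scale = num / den if den > 0 else 1.0
        self.empirical_csd = emp / self._scale
        self._weights = self._weights * self._scale
        self._d = self._features(self.empirical_csd)
        nf = self.freqs.size
        m = self.n * (self.n - 1) // 2  # upper-triangle entry count
        blocks = [self.n] + ([m, m] if m else [])  # diag, Re upper, Im upper
        self._freq_of_feature = np.concatenate(
            [np.repeat(np.arange(nf), b) for b in blocks]
        )
        self._noise_var = self._calibrate_noise()

    def _calibrate_noise(self) -> np.ndarray | None:
        """Per-frequency sampling variance of the spectral features.

        The empirical CSD is re-estimated on each half of the series; half-
        to-half feature differences, pooled within each frequency and
        lightly smoothed on the log scale, estimate the variance of the
        full-series features.  Using this fixed, data-derived noise level
        (instead of the fitted residuals) keeps the evidence honestly
        penalized for misfit and the posterior width tied to the actual
        estimator noise.
        """
        t = self.data.n_volumes
        halves = []
        for sl in (slice(0, t // 2), slice(t // 2, t)):
            half = RoiSeries(
                series=self.data.series[:, sl],
                tr=self.data.tr,
                roi_ids=self.data.roi_ids,
                provenance=self.data.provenance,
            )
            try:
                csd_h = mvar_csd(half, self.freqs, order=self.mvar_order)
            except ValueError:  # series too short to halve; fall back later
                return None
            halves.append(self._features(csd_h / self._scale))
        diff2 = (halves[0] - halves[1]) ** 2 / 4.0
        # pooled scalar level: per-frequency estimates from a single split
        # are too noisy (1 dof) to weight the bands individually
        return np.full(diff2.size, max(float(diff2.mean()), 1e-12))

    def _features(self, csd: np.ndarray) -> np.ndarray:
        return _features(csd * self._weights[:, None, None])

    def _predict(self, theta: np.ndarray) -> np.ndarray | None:
        params = _unpack(theta, self.n, self.priors.diag)
        if not params.is_stable():
            return None
        return self._features(forward_csd(params, self.freqs, self.use_hrf))

    def _free_energy(
        self, e: np.ndarray, v: np.ndarray, theta: np.ndarray,
        mu0: np.ndarray, P0_diag: np.ndarray, J: np.ndarray,
    ) -> float:
        dth = theta - mu0
        H = J.T @ (J / v[:, None]) + np.diag(P0_diag)
        sign, logdet_post = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf
        # F = log N(d | m, diag(v)) + log prior - log posterior  (Laplace)
        return float(
            -0.5 * np.sum(np.log(2 * math.pi * v))
            - 0.5 * e @ (e / v)
            - 0.5 * dth @ (P0_diag * dth)
            + 0.5 * np.sum(np.log(P0_diag))
            - 0.5 * logdet_post
        )

    def _jacobian(self, theta: np.ndarray, m: np.ndarray) -> np.ndarray:
        k = theta.size
        J = np.empty((m.size, k))
        step = 1e-5
        for p in range(k):
            th = theta.copy()
            th[p] += step
            mp = self._predict(th)
            if mp is None:  # perturbed model unstable; step the other way
                th[p] -= 2 * step
                mp = self._predict(th)
                if mp is None:
                    J[:, p] = 0.0
                    continue
                J[:, p] = (m - mp) / step
            else:
                J[:, p] = (mp - m) / step
        return J

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 64,
        tol: float = 1e-3,
    ) -> "CrossSpectralResults":
        """Gauss-Newton ascent on the Laplace free energy.

        Returns the posterior mean/covariance, the free energy (approximate
        log evidence) and the free-energy trajectory.  A fit that has not
        converged within ``maxiter`` iterations is returned flagged.
        """
        mu0, var0 = self.priors.pack(self.n)
        P0 = 1.0 / var0
        theta = mu0.copy() if start_params is None else np.asarray(start_params, float).copy()
        d = self._d
        m = self._predict(theta)
        if m is None:
            raise ValueError("starting parameters define an unstable system")
        e = d - m
        v = self._noise_var
        if v is None:  # series too short for the split-half calibration
            v = np.full(e.size, max(float(e @ e) / e.size, 1e-12))
        J = self._jacobian(theta, m)
        F = self._free_energy(e, v, theta, mu0, P0, J)
        trajectory = [F]
        lam = 1e-3
        converged = False
        for _ in range(maxiter):
            g = J.T @ (e / v) - P0 * (theta - mu0)
            H = J.T @ (J / v[:, None]) + np.diag(P0)
            accepted = False
            for _ in range(12):
                try:
                    delta = np.linalg.solve(H + lam * np.diag(np.diag(H)), g)
                except np.linalg.LinAlgError:
                    lam *= 8
                    continue
                th_new = theta + delta
                m_new = self._predict(th_new)
                if m_new is not None:
                    e_new = d - m_new
                    J_new = self._jacobian(th_new, m_new)
                    F_new = self._free_energy(e_new, v, th_new, mu0, P0, J_new)
                    if F_new >= F:
                        theta, m, e, J, F = (
                            th_new, m_new, e_new, J_new, F_new,
                        )
                        lam = max(lam / 2, 1e-8)
                        accepted = True
                        break
                lam *= 8
            trajectory.append(F)
            if not accepted:
                # no damped step improves F: a stationary point of the
                # free energy, i.e. convergence
                converged = True
                break
            if len(trajectory) > 1 and abs(trajectory[-1] - trajectory[-2]) < tol:
                converged = True
                break
        if not converged:
            logger.warning("cross-spectral fit did not converge; returning best iterate")
        H = J.T @ (J / v[:, None]) + np.diag(P0)
        cov = np.linalg.inv(H)
        return CrossSpectralResults(
            model=self,
            params=theta,
            cov=cov,
            evidence=F,
            prior_mean=mu0,
            prior_var=var0,
            noise_var=v,
            converged=converged,
            trajectory=np.array(trajectory),
        )


@dataclass
class CrossSpectralResults:
    """Posterior over cross-spectral model parameters for one subject."""

    model: CrossSpectralModel
    params: np.ndarray  # posterior mean of the free-parameter vector
    cov: np.ndarray  # posterior covariance
    evidence: float  # Laplace free energy (approximate log evidence)
    prior_mean: np.ndarray
    prior_var: np.ndarray
    noise_var: np.ndarray  # per-feature noise variance used in the likelihood
    converged: bool
    trajectory: np.ndarray = field(repr=False, default=None)

    @property
    def n_rois(self) -> int:
        return self.model.n

    def structural_params(self) -> CSDParams:
        return _unpack(self.params, self.model.n, self.model.priors.diag)

    @property
    def A(self) -> np.ndarray:
        """Posterior-mean connectivity (diagonal is the fixed self-decay)."""
        return self.structural_params().A

    def reduce(self, exhaustive_limit: int = 8) -> "ModelSpace":
        return bayesian_model_reduction(self, exhaustive_limit=exhaustive_limit)

    def summary(self) -> str:
        p = self.structural_params()
        lines = [
            "Cross-spectral connectivity model",
            "=================================",
            f"ROIs: {self.n_rois}   volumes: {self.model.data.n_volumes}   "
            f"TR: {self.model.data.tr:g} s",
            f"log evidence (free energy): {self.evidence:.2f}   "
            f"converged: {self.converged}",
            "effective connectivity A (1/s), row <- column:",
            pd.DataFrame(
                p.A, index=self.model.data.roi_ids, columns=self.model.data.roi_ids
            ).to_string(float_format=lambda v: f"{v:+.3f}"),
            "fluctuations: alpha_v="
            + np.array2string(p.alpha_v, precision=3)
            + "  beta_v="
            + np.array2string(p.beta_v, precision=3),
            f"noise: alpha_e={p.alpha_e:.3g}  beta_e={p.beta_e:.3g}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Bayesian model reduction and averaging
# ---------------------------------------------------------------------------


def _reduced_evidence(
    mu: np.ndarray,
    P: np.ndarray,
    mu0: np.ndarray,
    P0_diag: np.ndarray,
    off_mask: np.ndarray,
    reduced_var: float = REDUCED_PRIOR_VAR,
) -> tuple[float, np.ndarray]:
    """Closed-form change in log evidence when shrinking some priors to zero.

    ``off_mask`` marks parameters whose reduced prior is N(0, reduced_var).
    Returns ``(delta_F, reduced posterior mean)``.  Exact for a Gaussian
    posterior/prior pair.
    """
    P0r_diag = P0_diag.copy()
    P0r_diag[off_mask] = 1.0 / reduced_var
    mu0r = mu0.copy()
    mu0r[off_mask] = 0.0
    Pr = P + np.diag(P0r_diag - P0_diag)
    h = P @ mu + P0r_diag * mu0r - P0_diag * mu0
    sign_r, logdet_Pr = np.linalg.slogdet(Pr)
    sign_p, logdet_P = np.linalg.slogdet(P)
    if sign_r <= 0 or sign_p <= 0:
        logger.warning("ill-conditioned posterior in model reduction; regularizing")
        Pr = Pr + 1e-8 * np.eye(Pr.shape[0])
        sign_r, logdet_Pr = np.linalg.slogdet(Pr)
    mu_r = np.linalg.solve(Pr, h)
    dF = 0.5 * (
        logdet_P
        + np.sum(np.log(P0r_diag))
        - np.sum(np.log(P0_diag))
        - logdet_Pr
        + h @ mu_r
        - mu @ (P @ mu)
        - mu0r @ (P0r_diag * mu0r)
        + mu0 @ (P0_diag * mu0)
    )
    return float(dF), mu_r


@dataclass
class ModelSpace:
    """Evidences and reduced posteriors over on/off connection patterns."""

    results: CrossSpectralResults
    masks: list[frozenset]  # sets of off-switched (i, j) connections
    evidences: np.ndarray  # absolute log evidence per mask
    means: list[np.ndarray]  # reduced posterior mean per mask

    def average(self, cap: int = 256) -> np.ndarray:
        return bayesian_model_average(self, cap=cap)

    def best_mask(self) -> frozenset:
        return self.masks[int(np.argmax(self.evidences))]


def bayesian_model_reduction(
    full: CrossSpectralResults, exhaustive_limit: int = 8
) -> ModelSpace:
    """Score reduced models (connections switched off) without refitting.

    All ``2**m`` patterns are enumerated when the number of off-diagonal
    connections ``m`` is at most ``exhaustive_limit``; otherwise a greedy
    search prunes the connection whose removal most improves evidence until
    no removal improves it, scoring every visited pattern.
    """
    n = full.n_rois
    offs = _off_indices(n)
    P = np.linalg.inv(full.cov)
    P0_diag = 1.0 / full.prior_var
    mu, mu0 = full.params, full.prior_mean
    conn_to_param = {c: k for k, c in enumerate(offs)}

    def evaluate(mask: frozenset) -> tuple[float, np.ndarray]:
        off = np.zeros(mu.size, dtype=bool)
        for c in mask:
            off[conn_to_param[c]] = True
        dF, mu_r = _reduced_evidence(mu, P, mu0, P0_diag, off)
        return full.evidence + dF, mu_r

    masks: list[frozenset] = []
    evidences: list[float] = []
    means: list[np.ndarray] = []

    def record(mask: frozenset) -> float:
        ev, mu_r = evaluate(mask)
        masks.append(mask)
        evidences.append(ev)
        means.append(mu_r)
        return ev

    if len(offs) <= exhaustive_limit:
        for r in range(len(offs) + 1):
            for combo in itertools.combinations(offs, r):
                record(frozenset(combo))
    else:
        current: frozenset = frozenset()
        current_ev = record(current)
        remaining = set(offs)
        while remaining:
            cand = [(record(current | {c}), c) for c in sorted(remaining)]
            best_ev, best_c = max(cand, key=lambda t: t[0])
            if best_ev >= current_ev:
                current = current | {best_c}
                current_ev = best_ev
                remaining.discard(best_c)
            else:
                break
    return ModelSpace(
        results=full,
        masks=masks,
        evidences=np.array(evidences),
        means=means,
    )


def bayesian_model_average(space: ModelSpace, cap: int = 256) -> np.ndarray:
    """Evidence-weighted average connectivity over the best reduced models.

    Keeps at most ``cap`` patterns by evidence, weights them with a
    max-shifted exponential and averages the reduced posterior means.  The
    diagonal is excluded from averaging and reported as zero (self-coupling
    is fixed, not modelled).
    """
    if not space.masks:
        raise ValueError("empty model space")
    order = np.argsort(-space.evidences, kind="stable")[:cap]
    ev = space.evidences[order]
    w = np.exp(ev - ev.max())
    w = w / w.sum()
    n = space.results.n_rois
    offs = _off_indices(n)
    bma = np.zeros((n, n))
    for weight, idx in zip(w, order):
        mu_r = space.means[idx]
        for k, (i, j) in enumerate(offs):
            bma[i, j] += weight * mu_r[k]
    return bma


def outbound_excitation_score(bma_A: np.ndarray, roi_ids=None) -> pd.Series:
    """Per-ROI excitatory outbound dominance, min-max normalized to [0, 1].

    The raw score of ROI ``j`` is the sum of its positive outbound weights
    ``sum_i max(A[i, j], 0)`` over ``i != j``.  A flat raw profile yields
    all-zero scores with a warning.
    """
    A = np.asarray(bma_A, dtype=float)
    n = A.shape[0]
    off = A - np.diag(np.diag(A))
    raw = np.clip(off, 0.0, None).sum(axis=0)
    span = raw.max() - raw.min()
    if span <= 0:
        logger.warning("flat outbound-excitation profile; scores set to 0")
        scores = np.zeros(n)
    else:
        scores = (raw - raw.min()) / span
    index = roi_ids if roi_ids is not None else list(range(n))
    return pd.Series(scores, index=index, name="score_fmri")
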