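import logging

import numpy as np
import pytest

from imdnm.csd import CSDParams, forward_csd
from imdnm.data import RoiSeries


@pytest.fixture(autouse=True)
def _quiet_ridge_warnings(caplog):
    # the common-average reference makes window regressors exactly
    # rank-deficient by construction; the logged ridge fallback is expected
    logging.getLogger("imdnm.sourcesink").setLevel(logging.ERROR)
    yield


def make_bold_series(A, n_volumes, seed, alpha_v=1.0, beta_v=1.0,
                     alpha_e=0.5, beta_e=1.0, tr=2.0, use_hrf=True,
                     f_floor=1.0 / 128.0):
    """Frequency-domain synthesis of ROI series from explicit parameters.

    Mirrors the generative model directly (independent of imdnm.simulate)
    so fixture connectivity matrices can be planted exactly.
    """
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    p = CSDParams(A=A, alpha_v=alpha_v, beta_v=beta_v,
                  alpha_e=alpha_e, beta_e=beta_e)
    freqs = np.fft.rfftfreq(n_volumes, tr)[1:]
    S = forward_csd(p, np.maximum(freqs, f_floor), use_hrf=use_hrf)
    Y = np.zeros((n, n_volumes // 2 + 1), dtype=complex)
    scale = np.sqrt(n_volumes / tr)
    for k in range(freqs.size):
        L = np.linalg.cholesky(S[k] + 1e-12 * np.eye(n))
        xi = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
        Y[:, k + 1] = scale * (L @ xi)
    series = np.fft.irfft(Y, n=n_volumes, axis=1)
    return RoiSeries(series=series, tr=tr,
                     roi_ids=[f"R{i + 1}" for i in range(n)],
                     provenance="synthetic")


def random_stable_discrete_A(n, rng, radius=0.9):
    a = rng.standard_normal((n, n))
    return a * (radius / np.max(np.abs(np.linalg.eigvals(a))))
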