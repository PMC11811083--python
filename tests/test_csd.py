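"""Cross-spectral effective connectivity: forward model, spectral
estimators, fitting, Bayesian model reduction and averaging."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_bold_series
from imdnm.csd import (
    REDUCED_PRIOR_VAR,
    CrossSpectralModel,
    CSDParams,
    CSDPriors,
    _off_indices,
    bayesian_model_average,
    bayesian_model_reduction,
    default_freqs,
    eigenvariate,
    forward_csd,
    merge_rois,
    mvar_csd,
    outbound_excitation_score,
    welch_csd,
)
from imdnm.data import RoiMask
from imdnm.simulate import simulate_bold


def stable_params(A, **kw):
    n = A.shape[0]
    return CSDParams(
        A=A,
        alpha_v=kw.get("alpha_v", np.ones(n)),
        beta_v=kw.get("beta_v", np.ones(n)),
        alpha_e=kw.get("alpha_e", 0.5),
        beta_e=kw.get("beta_e", 1.0),
    )


class TestForwardCSD:
    def test_decoupled_lorentzian_closed_form(self):
        # diagonal A = -1, no hemodynamics, flat input spectra: the
        # auto-spectrum is alpha / (w^2 + 1) and cross-spectra vanish
        p = stable_params(
            -np.eye(3), beta_v=np.zeros(3), alpha_e=1e-12, beta_e=1.0
        )
        freqs = np.array([0.01, 0.05, 0.2])
        S = forward_csd(p, freqs, use_hrf=False)
        w = 2 * np.pi * freqs
        for k in range(3):
            expected = 1.0 / (w[k] ** 2 + 1.0)
            assert np.allclose(np.diag(S[k]).real, expected, rtol=1e-9)
            off = S[k] - np.diag(np.diag(S[k]))
            assert np.abs(off).max() < 1e-9

    def test_hermitian_psd_for_random_stable_models(self):
        rng = np.random.default_rng(0)
        freqs = default_freqs()
        for _ in range(10):
            n = rng.integers(2, 6)
            a = 0.3 * rng.standard_normal((n, n))
            np.fill_diagonal(a, -1.0)
            if np.max(np.linalg.eigvals(a).real) >= 0:
                continue
            S = forward_csd(stable_params(a), freqs)
            for k in range(freqs.size):
                assert np.allclose(S[k], S[k].conj().T)
                ev = np.linalg.eigvalsh(S[k])
                assert ev.min() >= -1e-10

    def test_unstable_model_refused(self):
        a = np.array([[0.1, 0.0], [0.0, -1.0]])
        with pytest.raises(ValueError, match="unstable"):
            forward_csd(stable_params(a), np.array([0.1]))

    def test_long_simulation_matches_periodogram_within_15pct(self):
        # windowed-periodogram CSD of long frequency-synthesized runs
        errs = []
        for seed in range(4):
            data, gt = simulate_bold(n_rois=3, n_volumes=8192, seed=200 + seed)
            p = stable_params(gt.true_A_fmri)
            f, S_emp = welch_csd(data, nperseg=64)
            band = (f >= 0.02) & (f <= 0.12)
            S_true = forward_csd(p, f[band])
            errs.append(
                np.abs(S_emp[band] - S_true).mean() / np.abs(S_true).mean()
            )
        assert np.mean(errs) < 0.15

    def test_mvar_csd_converges_with_series_length(self):
        freqs = default_freqs()
        mean_err = {}
        for n_vol in (256, 1024, 4096):
            errs = []
            for seed in range(20):
                data, gt = simulate_bold(
                    n_rois=3, n_volumes=n_vol, seed=100 + seed
                )
                S_true = forward_csd(stable_params(gt.true_A_fmri), freqs)
                S_emp = mvar_csd(data, freqs, order=8)
                mid = slice(4, 12)
                errs.append(
                    np.abs(S_emp[mid] - S_true[mid]).mean()
                    / np.abs(S_true[mid]).mean()
                )
            mean_err[n_vol] = np.mean(errs)
        assert mean_err[256] > mean_err[1024] > mean_err[4096]


class TestRoiSummaries:
    def test_identical_voxels_reproduce_their_series(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(120)
        voxels = np.tile(s, (10, 1))
        out = eigenvariate(voxels, stat=np.zeros(10), thresh=0.5)
        r = np.corrcoef(out, s)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)
        assert out.std() == pytest.approx(1.0)

    def test_sign_follows_dominant_group(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(200)
        big = np.tile(s, (8, 1)) + 0.1 * rng.standard_normal((8, 200))
        small = np.tile(-s, (2, 1)) + 0.1 * rng.standard_normal((2, 200))
        out = eigenvariate(
            np.vstack([big, small]), stat=np.zeros(10), thresh=0.5
        )
        assert np.corrcoef(out, big.mean(axis=0))[0, 1] > 0

    def test_no_passing_voxel_is_an_error(self):
        with pytest.raises(ValueError, match="looser threshold"):
            eigenvariate(np.zeros((4, 50)), stat=np.ones(4), thresh=0.5)

    def test_merge_identical_disjoint_and_nested_masks(self):
        grid = (4, 4, 4)
        m = lambda vox, rid: RoiMask(frozenset(vox), rid, grid)
        merged = merge_rois([m({0, 1, 2}, "a"), m({0, 1, 2}, "b")], 0.8)
        assert len(merged) == 1
        merged = merge_rois([m({0, 1}, "a"), m({10, 11}, "b")], 0.8)
        assert len(merged) == 2
        # A inside B: overlap relative to the smaller mask is 1
        merged = merge_rois([m({0, 1}, "a"), m({0, 1, 2, 3, 4}, "b")], 0.8)
        assert len(merged) == 1
        assert len(merged[0].voxels) == 5

    def test_merge_requires_common_grid(self):
        a = RoiMask({0}, "a", (2, 2, 2))
        b = RoiMask({0}, "b", (3, 3, 3))
        with pytest.raises(ValueError, match="grids"):
            merge_rois([a, b])


class TestFit:
    def test_single_roi_rejected(self):
        from imdnm.data import RoiSeries

        with pytest.raises(ValueError):
            RoiSeries(np.zeros((1, 100)), tr=2.0, roi_ids=["a"])

    def test_evidence_non_decreasing_from_truth(self):
        A = np.array([[-0.5, 0.2, 0.0], [0.1, -0.5, -0.2], [0.3, 0.0, -0.5]])
        data = make_bold_series(A, 600, seed=5)
        model = CrossSpectralModel(data)
        k_a = 6
        start = np.zeros(k_a + 2 * 3 + 2)
        offs = _off_indices(3)
        for k, (i, j) in enumerate(offs):
            start[k] = A[i, j]
        res = model.fit(start_params=start)
        diffs = np.diff(res.trajectory)
        assert (diffs >= -1e-9).all()

    def test_signed_connectivity_recovered(self):
        # planted signs of strong couplings recovered in >= 90% of runs
        ok = tot = 0
        for seed in range(25):
            data, gt = simulate_bold(n_rois=3, n_volumes=600, seed=1000 + seed)
            res = CrossSpectralModel(data).fit()
            for i in range(3):
                for j in range(3):
                    if i != j and abs(gt.true_A_fmri[i, j]) >= 0.3:
                        tot += 1
                        ok += np.sign(res.A[i, j]) == np.sign(
                            gt.true_A_fmri[i, j]
                        )
        assert ok / tot >= 0.9

    def test_summary_reports_connectivity(self):
        data, _ = simulate_bold(n_rois=2, n_volumes=256, seed=3)
        res = CrossSpectralModel(data).fit()
        text = res.summary()
        assert "effective connectivity" in text
        assert "log evidence" in text


@pytest.fixture(scope="module")
def full_fit():
    A = np.array([[-0.5, 0.1], [-0.1, -0.5]])
    data = make_bold_series(A, 600, seed=7)
    return data, CrossSpectralModel(data).fit()


class TestModelReduction:

    def test_identity_reduction_changes_nothing(self, full_fit):
        _, res = full_fit
        space = bayesian_model_reduction(res)
        ev_empty = space.evidences[space.masks.index(frozenset())]
        assert ev_empty == pytest.approx(res.evidence, abs=1e-9)

    def test_two_roi_enumeration_has_four_masks(self, full_fit):
        _, res = full_fit
        space = bayesian_model_reduction(res)
        assert len(space.masks) == 4

    def test_closed_form_matches_refit_within_one_nat(self, full_fit):
        data, res = full_fit
        space = bayesian_model_reduction(res)
        offs = _off_indices(2)
        conn = {c: k for k, c in enumerate(offs)}
        mu0, var0 = res.prior_mean, res.prior_var
        for mask, ev in zip(space.masks, space.evidences):
            var_red = var0.copy()
            for c in mask:
                var_red[conn[c]] = REDUCED_PRIOR_VAR

            class Reduced(CSDPriors):
                def pack(self, n, _v=var_red):
                    return mu0.copy(), _v

            m = CrossSpectralModel(data)
            m.priors = Reduced()
            refit = m.fit()
            assert abs(float(ev) - refit.evidence) < 1.0

    def test_null_connection_pruned(self):
        # structure recovery: the one absent coupling is switched off
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            A = 0.15 * rng.choice([-1.0, 1.0], size=(3, 3))
            np.fill_diagonal(A, -0.5)
            A[0, 1] = 0.0
            data = make_bold_series(A, 4800, seed=3000 + seed)
            best = CrossSpectralModel(data).fit().reduce().best_mask()
            hits += (0, 1) in best
        assert hits / 25 >= 0.9


class TestModelAveraging:
    def _space(self, evidences, means, n=3):
        from imdnm.csd import ModelSpace

        class Dummy:
            n_rois = n

        return ModelSpace(
            results=Dummy(),
            masks=[frozenset() for _ in evidences],
            evidences=np.asarray(evidences, dtype=float),
            means=[np.asarray(m, dtype=float) for m in means],
        )

    def test_single_model_returns_its_mean(self):
        mu = np.arange(14, dtype=float)
        bma = bayesian_model_average(self._space([1.0], [mu]))
        offs = _off_indices(3)
        for k, (i, j) in enumerate(offs):
            assert bma[i, j] == mu[k]
        assert np.allclose(np.diag(bma), 0.0)

    def test_equal_evidence_is_arithmetic_mean(self):
        a = np.zeros(14)
        b = np.ones(14)
        bma = bayesian_model_average(self._space([2.0, 2.0], [a, b]))
        offs = _off_indices(3)
        for i, j in offs:
            assert bma[i, j] == pytest.approx(0.5)

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(4)
        ev = rng.standard_normal(10)
        means = [rng.standard_normal(14) for _ in range(10)]
        bma = bayesian_model_average(self._space(list(ev), means))
        w = np.exp(ev - ev.max())
        w = w / w.sum()
        brute = sum(wi * m for wi, m in zip(w, means))
        offs = _off_indices(3)
        for k, (i, j) in enumerate(offs):
            assert abs(bma[i, j] - brute[k]) < 1e-12

    def test_cap_keeps_best_models(self):
        means = [np.full(14, float(i)) for i in range(5)]
        ev = [0.0, 1.0, 2.0, 3.0, 100.0]
        bma = bayesian_model_average(self._space(ev, means), cap=1)
        assert bma[0, 1] == 4.0


class TestOutboundScore:
    def test_unique_positive_sender_scores_one(self):
        A = np.array(
            [[0.0, -0.2, 0.1], [0.5, 0.0, -0.1], [0.4, -0.3, 0.0]]
        )
        s = outbound_excitation_score(A, ["a", "b", "c"])
        assert s["a"] == 1.0  # only ROI with large positive outbound column

    def test_all_negative_warns_to_zero(self, caplog):
        A = -np.ones((3, 3))
        s = outbound_excitation_score(A)
        assert (s == 0).all()

    def test_matches_hand_computed_column_sums(self):
        A = np.array(
            [[0.0, 0.3, -0.1], [0.2, 0.0, 0.4], [-0.5, 0.1, 0.0]]
        )
        raw = np.array(
            [0.2, 0.3 + 0.1, 0.4]  # positive parts of each column, off-diag
        )
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        s = outbound_excitation_score(A)
        assert np.allclose(s.to_numpy(), expected)
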