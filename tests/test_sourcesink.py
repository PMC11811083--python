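"""Dynamic network estimation and source-sink index computation."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_stable_discrete_A
from imdnm.data import Recording
from imdnm.sourcesink import (
    SourceSinkModel,
    aggregate_A,
    channel_to_roi,
    estimate_window_A,
    source_sink_space,
    ssi_scores,
)

SQRT2 = math.sqrt(2.0)


class TestEstimateWindowA:
    def test_exact_recovery_on_noise_free_dynamics(self):
        rng = np.random.default_rng(0)
        A0 = random_stable_discrete_A(5, rng, radius=0.9)
        x = np.empty((5, 50))
        x[:, 0] = rng.standard_normal(5)
        for t in range(49):
            x[:, t + 1] = A0 @ x[:, t]
        A, resid = estimate_window_A(x)
        assert np.max(np.abs(A - A0)) < 1e-8
        assert resid < 1e-16

    def test_fixed_point_system_returns_identity(self):
        # x(t+1) = x(t) plus tiny jitter: the fitted map is the identity
        rng = np.random.default_rng(1)
        x = np.empty((3, 400))
        x[:, 0] = [1.0, 2.0, 3.0]
        for t in range(399):
            x[:, t + 1] = x[:, t] + 1e-4 * rng.standard_normal(3)
        A, _ = estimate_window_A(x)
        assert np.allclose(A, np.eye(3), atol=0.05)

    def test_all_zero_window_gives_zero_matrix(self, caplog):
        A, resid = estimate_window_A(np.zeros((3, 20)))
        assert np.array_equal(A, np.zeros((3, 3)))
        assert resid == 0.0

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="cannot identify"):
            estimate_window_A(np.zeros((5, 5)))

    def test_error_shrinks_with_more_data(self):
        # least-squares consistency under process noise
        rng = np.random.default_rng(7)
        A0 = random_stable_discrete_A(4, rng, radius=0.9)

        def err(w, seed):
            r = np.random.default_rng(seed)
            x = np.zeros((4, w))
            for t in range(w - 1):
                x[:, t + 1] = A0 @ x[:, t] + r.standard_normal(4)
            A, _ = estimate_window_A(x)
            return np.max(np.abs(A - A0))

        short = np.mean([err(100, s) for s in range(30)])
        long = np.mean([err(2000, s) for s in range(30)])
        assert long < short


class TestAggregate:
    def test_single_matrix(self):
        m = np.array([[1.0, -2.0], [3.0, -4.0]])
        assert np.array_equal(aggregate_A([m]), np.abs(m))

    def test_sign_symmetry(self):
        m = np.random.default_rng(0).standard_normal((4, 4))
        assert np.allclose(aggregate_A([m, -m]), np.abs(m))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        seq = [rng.standard_normal((5, 5)) for _ in range(3)]
        brute = sum(np.abs(a) for a in seq) / 3.0
        assert np.max(np.abs(aggregate_A(seq) - brute)) < 1e-14

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_A([np.zeros((2, 2)), np.zeros((3, 3))])


class TestSourceSinkSpace:
    def test_two_node_hand_computation(self):
        rr, cr = source_sink_space(np.array([[0.0, 5.0], [1.0, 0.0]]))
        # row strengths (5, 1) -> ranks (2, 1); column strengths (1, 5)
        assert np.allclose(rr, [1.0, 0.5])
        assert np.allclose(cr, [0.5, 1.0])

    def test_identical_channels_all_tied(self):
        n = 6
        a = np.ones((n, n))
        rr, cr = source_sink_space(a)
        assert np.allclose(rr, (n + 1) / (2 * n))
        assert np.allclose(cr, (n + 1) / (2 * n))

    def test_diagonal_excluded(self):
        rr, cr = source_sink_space(np.diag([9.0, 1.0, 4.0]))
        assert np.allclose(rr, rr[0])  # all strengths zero -> all tied
        assert np.allclose(cr, cr[0])


def brute_force_indices(A_bar, q):
    """Independent re-implementation of the four indices with plain loops."""
    n = A_bar.shape[0]
    r = [sum(A_bar[i, j] for j in range(n) if j != i) for i in range(n)]
    c = [sum(A_bar[i, j] for i in range(n) if i != j) for j in range(n)]

    def ranks(v):
        out = []
        for x in v:
            less = sum(1 for y in v if y < x)
            eq = sum(1 for y in v if y == x)
            out.append((less + (less + eq + 1)) / 2 / n)  # average rank / n
        return out

    rr, cr = ranks(r), ranks(c)
    si = [SQRT2 - math.hypot(rr[i] - 1, cr[i] - 1 / n) for i in range(n)]
    src = [SQRT2 - math.hypot(rr[i] - 1 / n, cr[i] - 1) for i in range(n)]
    k = math.ceil(q * n)
    top_src = sorted(range(n), key=lambda i: -src[i])[:k]
    top_sink = sorted(range(n), key=lambda i: -si[i])[:k]
    sf = [
        np.mean([A_bar[i, s] for s in top_src if s != i])
        if [s for s in top_src if s != i]
        else 0.0
        for i in range(n)
    ]
    sc = [
        np.mean([A_bar[i, s] for s in top_sink if s != i])
        if [s for s in top_sink if s != i]
        else 0.0
        for i in range(n)
    ]
    raw = np.array(si) * np.array(sf) * np.array(sc)
    return (raw - raw.min()) / (raw.max() - raw.min())


class TestSSI:
    # channels 2 and 3 receive the strong entries (from each other too) and
    # send little: a pair of interconnected sinks, as the onset-zone
    # hypothesis describes
    TOY = np.array(
        [
            [0.0, 0.3, 0.05, 0.06],
            [0.25, 0.0, 0.1, 0.08],
            [0.9, 0.8, 0.0, 0.85],
            [0.88, 0.82, 0.8, 0.0],
        ]
    )

    def test_ideal_sink_corner_attains_sqrt2(self):
        n = 4
        rr = np.array([1.0, 0.25, 0.5, 0.75])
        cr = np.array([1.0 / n, 0.5, 0.75, 1.0])
        df = ssi_scores(rr, cr, self.TOY, q=0.25)
        assert df["sink_index"].iloc[0] == pytest.approx(SQRT2)

    def test_toy_receiver_scores_one(self):
        rr, cr = source_sink_space(self.TOY)
        df = ssi_scores(rr, cr, self.TOY, q=0.5)
        assert df["ssi"].idxmax() == 2
        assert df["ssi"].max() == pytest.approx(1.0)

    def test_matches_brute_force_on_toy(self):
        rr, cr = source_sink_space(self.TOY)
        df = ssi_scores(rr, cr, self.TOY, q=0.5)
        expected = brute_force_indices(self.TOY, 0.5)
        assert np.allclose(df["ssi"].to_numpy(), expected, atol=1e-12)

    def test_top_set_sizes(self):
        a = np.array([[0.0, 1.0], [2.0, 0.0]])
        rr, cr = source_sink_space(a)
        df = ssi_scores(rr, cr, a, q=0.5)
        assert int(df["top_source"].sum()) == 1
        assert int(df["top_sink"].sum()) == 1

    def test_bounds_hold_on_random_networks(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = np.abs(rng.standard_normal((8, 8)))
            rr, cr = source_sink_space(a)
            df = ssi_scores(rr, cr, a)
            assert (df["sink_index"] >= 0).all()
            assert (df["sink_index"] <= SQRT2 + 1e-12).all()
            assert (df["ssi"] >= 0).all() and (df["ssi"] <= 1).all()
            assert df["ssi"].max() == pytest.approx(1.0)

    def test_all_zero_network_warns_and_zeroes(self, caplog):
        a = np.zeros((4, 4))
        rr, cr = source_sink_space(a)
        df = ssi_scores(rr, cr, a)
        assert (df["ssi"] == 0).all()

    def test_invalid_top_fraction(self):
        rr, cr = source_sink_space(self.TOY)
        with pytest.raises(ValueError, match="top fraction"):
            ssi_scores(rr, cr, self.TOY, q=0.7)


class TestChannelToRoi:
    def _scores(self, vals):
        return pd.DataFrame(
            {"ssi": vals}, index=[f"c{i}" for i in range(len(vals))]
        )

    def test_mean_within_roi(self):
        s = channel_to_roi(
            self._scores([0.2, 0.8]), {"c0": "R1", "c1": "R1"}
        )
        assert s["R1"] == pytest.approx(0.5)

    def test_singleton_roi(self):
        s = channel_to_roi(self._scores([0.3, 0.9]), {"c1": "R2"})
        assert s["R2"] == pytest.approx(0.9)

    def test_empty_map(self):
        s = channel_to_roi(self._scores([0.3]), {})
        assert len(s) == 0


class TestModel:
    def _recording(self, seed=0, n=6, samples=3000):
        rng = np.random.default_rng(seed)
        A0 = random_stable_discrete_A(n, rng, radius=0.9)
        x = np.zeros((n, samples))
        for t in range(samples - 1):
            x[:, t + 1] = A0 @ x[:, t] + rng.standard_normal(n)
        return Recording(
            signal=50 * x, fs=1000, labels=[f"c{i}" for i in range(n)]
        )

    def test_label_equivariance(self):
        rec = self._recording()
        perm = [3, 0, 5, 1, 4, 2]
        rec_p = Recording(
            signal=rec.signal[perm],
            fs=rec.fs,
            labels=[rec.labels[i] for i in perm],
        )
        kw = dict(band=None, notch_band=None, car=False)
        a = SourceSinkModel(rec, **kw).fit().channel_scores
        b = SourceSinkModel(rec_p, **kw).fit().channel_scores
        for lab in rec.labels:
            assert a.loc[lab, "ssi"] == pytest.approx(
                b.loc[lab, "ssi"], abs=1e-12
            )

    def test_aggregate_matches_mean_abs_invariant(self):
        res = SourceSinkModel(
            self._recording(1), band=None, notch_band=None, car=False
        ).fit()
        brute = np.mean([np.abs(a) for a in res.dnm.A_seq], axis=0)
        assert np.max(np.abs(res.A_bar - brute)) < 1e-12
        assert (res.A_bar >= 0).all()
        assert res.dnm.T == len(res.dnm.A_seq)

    def test_summary_mentions_windows_and_channels(self):
        res = SourceSinkModel(
            self._recording(2), band=None, notch_band=None, car=False
        ).fit()
        text = res.summary()
        assert "channels: 6" in text
        assert "windows:" in text
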