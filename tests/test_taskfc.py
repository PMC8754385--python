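import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinconn import (
    ConditionWeights,
    RoiTimeSeries,
    bandpass_filter,
    canonical_hrf,
    condition_contrast,
    condition_weight_series,
    network_summary,
    regress_confounds,
    simulate_task_events,
    weighted_fc,
)
from twinconn.containers import CS_PLUS_NOUS, CS_PLUS_US, US


class TestCanonicalHrf:
    def test_peak_near_five_seconds(self):
        h = canonical_hrf(0.1)
        assert np.argmax(h) * 0.1 == pytest.approx(5.0, abs=0.5)

    def test_sample_count_at_tr(self):
        assert len(canonical_hrf(2.4)) == int(np.floor(32 / 2.4)) + 1

    def test_zero_at_onset_and_unit_positive_mass(self):
        h = canonical_hrf(0.5)
        assert h[0] == 0.0
        assert h[h > 0].sum() == pytest.approx(1.0)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestConditionWeights:
    def test_disjoint_conditions_have_disjoint_peak_frames(self):
        ev = simulate_task_events(seed=3)
        n, tr = 250, 2.4
        wa = condition_weight_series(ev, [CS_PLUS_US, US], n, tr).weights
        wb = condition_weight_series(ev, CS_PLUS_NOUS, n, tr).weights
        # frames dominated by condition A should not be the top frames of B
        top_a = set(np.argsort(wa)[-10:])
        top_b = set(np.argsort(wb)[-10:])
        assert not (top_a & top_b)

    def test_weights_decay_after_last_event(self):
        ev = pd.DataFrame(
            {"onset": [10.0], "duration": [6.0], "trial_type": [CS_PLUS_US]}
        )
        w = condition_weight_series(ev, CS_PLUS_US, 100, 1.0).weights
        assert w[60:].max() < 1e-6 * w.max()

    def test_absent_condition_rejected(self):
        ev = simulate_task_events(seed=3)
        with pytest.raises(ValueError):
            condition_weight_series(ev, "no_such_condition", 100, 2.4)

    def test_nonnegative_and_not_all_zero(self):
        ev = simulate_task_events(seed=5)
        w = condition_weight_series(ev, CS_PLUS_NOUS, 250, 2.4)
        assert (w.weights >= 0).all() and w.weights.max() > 0


class TestRegressConfounds:
    def test_intercept_only_mean_centers(self):
        rng = np.random.default_rng(0)
        ts = RoiTimeSeries(rng.normal(5, 1, size=(50, 3)), tr=1.0)
        out = regress_confounds(ts, np.empty((50, 0)))
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        ts = RoiTimeSeries(rng.normal(size=(80, 4)), tr=1.0)
        conf = rng.normal(size=(80, 5))
        out = regress_confounds(ts, conf)
        inner = conf.T @ out.data
        scale = np.abs(conf).max() * np.abs(ts.data).max()
        assert np.abs(inner).max() / scale < 1e-8

    def test_scrub_regressor_zeroes_volume(self):
        rng = np.random.default_rng(2)
        ts = RoiTimeSeries(rng.normal(size=(40, 3)), tr=1.0)
        onehot = np.zeros((40, 1))
        onehot[17] = 1.0
        out = regress_confounds(ts, onehot)
        assert np.allclose(out.data[17], 0.0, atol=1e-10)

    def test_collinear_columns_dropped(self, caplog):
        rng = np.random.default_rng(3)
        ts = RoiTimeSeries(rng.normal(size=(30, 2)), tr=1.0)
        x = rng.normal(size=30)
        conf = np.column_stack([x, 2 * x])
        with caplog.at_level("WARNING", logger="twinconn"):
            out = regress_confounds(ts, conf)
        assert "collinear" in caplog.text
        assert np.abs(conf.T @ out.data).max() < 1e-8 * np.abs(conf).max() * np.abs(ts.data).max()


class TestBandpass:
    def _amp(self, x, f):
        freqs = np.fft.rfftfreq(len(x), 1.0)
        return np.abs(np.fft.rfft(x))[np.argmin(np.abs(freqs - f))]

    def test_band_edges(self):
        t = np.arange(500)
        inband = np.sin(2 * np.pi * 0.04 * t)
        low = np.sin(2 * np.pi * 0.004 * t)
        high = np.sin(2 * np.pi * 0.15 * t)
        sig = (inband + low + high)[:, None]
        out = bandpass_filter(RoiTimeSeries(sig, tr=1.0)).data[:, 0]
        assert self._amp(out, 0.04) / self._amp(inband, 0.04) >= 0.9
        assert self._amp(out, 0.004) / self._amp(low, 0.004) <= 0.1
        assert self._amp(out, 0.15) / self._amp(high, 0.15) <= 0.1

    def test_dc_removed_and_idempotent(self):
        rng = np.random.default_rng(4)
        ts = RoiTimeSeries(rng.normal(10, 1, size=(128, 2)), tr=1.0)
        once = bandpass_filter(ts)
        twice = bandpass_filter(once)
        assert abs(once.data.mean()) < 1e-10
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_cutoff_above_nyquist_rejected(self):
        ts = RoiTimeSeries(np.zeros((10, 1)) + np.arange(10)[:, None], tr=2.4)
        with pytest.raises(ValueError):
            bandpass_filter(ts, 0.008, 0.3)


class TestWeightedFC:
    def test_constant_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 6))
        z = weighted_fc(RoiTimeSeries(X, tr=1.0), ConditionWeights(np.ones(100), "c"))
        r = np.corrcoef(X.T)
        np.fill_diagonal(r, 0.0)
        expect = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
        assert np.abs(z - expect).max() < 1e-10

    def test_block_weights_equal_block_correlation(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(120, 4))
        w = np.zeros(120)
        w[30:60] = 1.0
        z = weighted_fc(RoiTimeSeries(X, tr=1.0), ConditionWeights(w, "c"))
        r = np.corrcoef(X[30:60].T)
        np.fill_diagonal(r, 0.0)
        expect = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
        assert np.abs(z - expect).max() < 1e-10

    def test_identical_nodes_clip_not_inf(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        X = np.column_stack([x, x, rng.normal(size=100)])
        z = weighted_fc(RoiTimeSeries(X, tr=1.0), ConditionWeights(np.ones(100), "c"))
        assert np.isfinite(z).all()
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=15, deadline=None)
    def test_affine_invariance_of_node_series(self, scale, shift):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        Y = X.copy()
        Y[:, 0] = scale * Y[:, 0] + shift
        w = ConditionWeights(rng.random(60) + 0.1, "c")
        za = weighted_fc(RoiTimeSeries(X, tr=1.0), w)
        zb = weighted_fc(RoiTimeSeries(Y, tr=1.0), w)
        assert np.allclose(za, zb, atol=1e-10)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 3))
        w = rng.random(60) + 0.1
        za = weighted_fc(RoiTimeSeries(X, tr=1.0), ConditionWeights(w, "c"))
        zb = weighted_fc(RoiTimeSeries(X, tr=1.0), ConditionWeights(7.3 * w, "c"))
        assert np.allclose(za, zb, atol=1e-12)

    def test_zero_variance_node_zeroed(self, caplog):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 3))
        X[:, 1] = 4.2
        with caplog.at_level("WARNING", logger="twinconn"):
            z = weighted_fc(RoiTimeSeries(X, tr=1.0), ConditionWeights(np.ones(50), "c"))
        assert np.allclose(z[1, :], 0) and np.allclose(z[:, 1], 0)


class TestContrastAndSummary:
    def test_contrast_of_equal_matrices_is_zero(self):
        m = np.random.default_rng(11).normal(size=(5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        assert np.allclose(condition_contrast(m, m), 0)

    def test_contrast_antisymmetry_and_shape_check(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        assert np.allclose(condition_contrast(a, b), -condition_contrast(b, a))
        with pytest.raises(ValueError):
            condition_contrast(a, np.zeros((3, 3)))

    def test_network_summary_hand_examples(self):
        m = np.zeros((4, 4))
        for i in (0, 1):
            for j in (2, 3):
                m[i, j] = m[j, i] = 1.0
        s = network_summary(m, ["A", "A", "B", "B"])
        assert s.loc["A", "B"] == pytest.approx(1.0)  # 4 edges / (2+2)
        m2 = np.zeros((4, 4))
        m2[0, 1] = m2[1, 0] = 0.6
        s2 = network_summary(m2, ["A", "A", "B", "B"])
        assert s2.loc["A", "A"] == pytest.approx(0.3)  # v / |A|
        assert np.allclose(network_summary(np.zeros((4, 4)), ["A", "A", "B", "B"]), 0)

    def test_unlabeled_node_rejected(self):
        with pytest.raises(ValueError):
            network_summary(np.zeros((3, 3)), ["A", None, "B"])
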