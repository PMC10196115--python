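"""Connectivity tests: PLV identities and null bias, sliding-correlation
bounds, cross-correlation against a brute-force oracle, and lag recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from painlfp.connectivity import (
    below_baseline_recovery,
    cross_correlation,
    estimate_interhemispheric_lag,
    expected_null_plv,
    plv_timefreq,
    sliding_correlation,
)
from painlfp.datatypes import SimConfig, TrialSet
from painlfp.errors import DegenerateInputError, InvalidArgumentError
from painlfp.simulate import generate_trial_set

FS = 1000.0


def _trialset(left, right, onset=0):
    sig = np.stack([left, right], axis=1)
    n = sig.shape[0]
    return TrialSet(sig, FS, np.full(n, onset), np.array(["HN"] * n),
                    np.full(n, np.nan), np.zeros(n, dtype=int),
                    np.array(["s0"] * n))


class TestPLV:
    def test_identical_signals_plv_one(self, rng):
        x = rng.standard_normal((3, 2000))
        m = plv_timefreq(x, x, FS, freqs=np.array([8.0, 30.0]), onset_idx=500)
        assert np.allclose(m.plv, 1.0)
        assert m.plv.min() >= 0.0 and m.plv.max() <= 1.0

    def test_constant_phase_offset_plv_one(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        y = np.sin(2 * np.pi * 10.0 * t + 1.1)[None, :]
        m = plv_timefreq(x, y, FS, freqs=np.array([10.0]), onset_idx=1000)
        interior = m.plv[0, (m.times > -0.5) & (m.times < 1.5)]
        assert np.all(interior > 0.99)

    @pytest.mark.parametrize("n", [50, 200, 1000])
    def test_null_bias_follows_rayleigh_law(self, n, rng):
        # direct Monte-Carlo over independent uniform phases
        reps = 400
        phases = rng.uniform(0, 2 * np.pi, size=(reps, n))
        plv = np.abs(np.exp(1j * phases).mean(axis=1)).mean()
        assert plv == pytest.approx(expected_null_plv(n), rel=0.1)

    @settings(deadline=None, max_examples=10)
    @given(scale=hst.floats(0.01, 100.0))
    def test_amplitude_scaling_invariance(self, scale):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2, 1500))
        y = rng.standard_normal((2, 1500))
        m1 = plv_timefreq(x, y, FS, freqs=np.array([12.0]), onset_idx=500)
        m2 = plv_timefreq(scale * x, y, FS, freqs=np.array([12.0]), onset_idx=500)
        assert np.allclose(m1.plv, m2.plv, atol=1e-9)

    def test_window_longer_than_epoch_rejected(self, rng):
        x = rng.standard_normal((2, 300))
        with pytest.raises(InvalidArgumentError):
            plv_timefreq(x, x, FS, freqs=np.array([10.0]), window_ms=500.0)


class TestSlidingCorrelation:
    def test_identical_signals_trace_one(self, rng):
        x = rng.standard_normal((4, 2000))
        tr = sliding_correlation(x, x, FS, onset_idx=500)
        assert np.allclose(tr.mean, 1.0)

    def test_sign_flipped_signals_trace_minus_one(self, rng):
        x = rng.standard_normal((4, 2000))
        tr = sliding_correlation(x, -x, FS, onset_idx=500)
        assert np.allclose(tr.mean, -1.0)

    def test_independent_noise_near_zero(self, rng):
        n_trials, w = 60, 500
        x = rng.standard_normal((n_trials, 3000))
        y = rng.standard_normal((n_trials, 3000))
        tr = sliding_correlation(x, y, FS, onset_idx=1000, baseline_s=None)
        band = 3.0 / np.sqrt(w * n_trials)
        assert np.abs(tr.mean).mean() < band

    def test_zero_variance_window_counted(self, rng):
        x = rng.standard_normal((2, 1500))
        y = x.copy()
        y[0, :700] = 5.0  # constant stretch -> undefined windows
        tr = sliding_correlation(x, y, FS, onset_idx=100, baseline_s=None)
        assert tr.n_undefined > 0
        assert np.nanmax(np.abs(tr.per_trial)) <= 1.0


class TestCrossCorrelation:
    def test_known_delay_recovered(self, rng):
        x = rng.standard_normal(5000)
        y = np.roll(x, 12)
        cc = cross_correlation(x, y, 50, fs=FS)
        assert cc.lags[np.argmax(cc.r)] == 12
        assert cc.lag_at_max_ms == pytest.approx(12.0)

    def test_self_correlation_unity_at_zero(self, rng):
        x = rng.standard_normal(2000)
        cc = cross_correlation(x, x, 20, fs=FS)
        assert cc.r[20] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(cc.r) <= 1.0 + 1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(240)
        y = rng.standard_normal(240)
        max_lag = 15
        cc = cross_correlation(x, y, max_lag, fs=FS)
        xc, yc = x - x.mean(), y - y.mean()
        T = len(x)
        sx = np.sqrt(np.mean(xc ** 2))
        sy = np.sqrt(np.mean(yc ** 2))
        for k in range(-max_lag, max_lag + 1):
            if k >= 0:
                c = sum(xc[i] * yc[i + k] for i in range(T - k)) / T
            else:
                c = sum(yc[i] * xc[i - k] for i in range(T + k)) / T
            assert cc.r[max_lag + k] == pytest.approx(c / (sx * sy), abs=1e-12)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cross_correlation(np.ones(100), np.arange(100.0), 5)


class TestLagEstimation:
    def test_shared_source_lag_zero(self):
        cfg = SimConfig(n_trials={"HN": 40}, seed=2, artifact_rate=0.0)
        ts = generate_trial_set(cfg)
        est = estimate_interhemispheric_lag(ts, max_lag_ms=50.0)
        assert est.lag_ms == 0.0

    def test_injected_delay_recovered(self):
        cfg = SimConfig(n_trials={"HN": 40}, seed=2, artifact_rate=0.0)
        ts = generate_trial_set(cfg)
        ts.signals[:, 1, :] = np.roll(ts.signals[:, 1, :], 10, axis=-1)
        est = estimate_interhemispheric_lag(ts, max_lag_ms=50.0)
        assert est.lag_ms == pytest.approx(10.0)

    def test_independent_hemispheres_flagged_unreliable(self, rng):
        left = rng.standard_normal((20, 2000))
        right = rng.standard_normal((20, 2000))
        ts = _trialset(left, right, onset=500)
        est = estimate_interhemispheric_lag(ts, max_lag_ms=30.0,
                                            n_permutations=40, rng=rng)
        assert not est.reliable


class TestRecoveryReadout:
    def test_synthetic_dip_end_detected(self):
        times = np.arange(-2.0, 6.0, 0.01)
        trace = np.full_like(times, 0.8)
        dip = (times > 0.5) & (times < 3.8)
        trace[dip] -= 0.3 * (1 - (times[dip] - 0.5) / 3.3)
        rec = below_baseline_recovery(times, trace, k=2.0)
        assert rec == pytest.approx(3.8, abs=0.3)

    def test_flat_trace_returns_none(self, rng):
        times = np.arange(-2.0, 6.0, 0.01)
        trace = 0.8 + 0.001 * rng.standard_normal(times.size)
        assert below_baseline_recovery(times, trace) is None
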