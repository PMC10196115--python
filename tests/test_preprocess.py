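"""Preprocessing tests: filters, z-scoring, Grubbs rejection, channel
averaging, epoching, and the zero-phase/idempotence properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from painlfp.datatypes import DEFAULT_EP_TEMPLATES, SimConfig
from painlfp.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidArgumentError,
    UnusableHemisphereError,
)
from painlfp.preprocess import (
    average_hemisphere_channels,
    bandpass,
    epoch,
    grubbs_outlier_mask,
    notch,
    preprocess_trialset,
    reject_trials,
    zscore,
    zscore_session,
)
from painlfp.simulate import generate_trial_set, inject_artifacts, make_ep_template

FS = 1000.0


def _tone(freq, n=4000, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestBandpass:
    def test_passband_tone_preserved(self):
        out = bandpass(_tone(50.0, n=8000), FS)
        interior = out[2000:-2000]  # clear of filtfilt edge transients
        amp = np.sqrt(2.0 * (interior ** 2).mean())
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_subband_tone_attenuated(self):
        out = bandpass(_tone(1.0, n=8000), FS)
        assert np.abs(out[1000:-1000]).max() < 0.05

    def test_dc_removed(self):
        out = bandpass(np.full(4000, 3.0), FS)
        assert np.abs(out).max() < 1e-6

    def test_invalid_edges(self):
        with pytest.raises(InvalidArgumentError):
            bandpass(_tone(10), FS, lo=3, hi=600)


class TestNotch:
    def test_mains_suppressed(self):
        x = _tone(50.0)
        out = notch(x, FS)
        assert np.sqrt((out ** 2).mean()) < 0.1 * np.sqrt((x ** 2).mean())

    def test_neighbor_preserved(self):
        x = _tone(40.0)
        out = notch(x, FS)
        assert np.sqrt((out ** 2).mean()) > 0.7 * np.sqrt((x ** 2).mean())

    def test_zero_in_zero_out(self):
        assert np.allclose(notch(np.zeros(2000), FS), 0.0)


class TestZscore:
    def test_three_point_example(self):
        z, p = zscore(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.0, 0.0, 1.0])
        assert p.mean == 2.0 and p.sd == 1.0

    @settings(deadline=None, max_examples=25)
    @given(a=hst.floats(0.1, 50.0), b=hst.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, b):
        x = np.sin(np.arange(64) / 3.0)
        z1, _ = zscore(x)
        z2, _ = zscore(a * x + b)
        assert np.allclose(z1, z2, atol=1e-9)

    def test_postconditions(self, rng):
        z, _ = zscore(rng.normal(3.0, 2.5, size=500))
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateInputError):
            zscore(np.ones(10))

    def test_session_zscore_exactly_idempotent(self, small_trialset):
        once, _ = zscore_session(small_trialset)
        twice, _ = zscore_session(once)
        assert np.allclose(once.signals, twice.signals, atol=1e-9)


class TestGrubbs:
    def test_single_gross_outlier_flagged(self, rng):
        x = rng.normal(size=30)
        x[13] = 15.0
        mask = grubbs_outlier_mask(x)
        assert mask[13]
        assert mask.sum() == 1

    def test_no_outliers_empty_mask(self):
        x = np.sin(np.arange(50) / 5.0) * 0.01
        assert grubbs_outlier_mask(x).sum() == 0

    def test_false_positive_rate_controlled(self, rng):
        fracs = [grubbs_outlier_mask(rng.normal(size=3000)).mean() for _ in range(5)]
        assert np.mean(fracs) < 0.02

    def test_needs_seven_samples(self):
        with pytest.raises(InsufficientDataError):
            grubbs_outlier_mask(np.arange(5.0))


class TestRejectTrials:
    def test_injected_artifacts_rejected_exactly(self, small_trialset, rng):
        dirty, ids = inject_artifacts(small_trialset, 0.1, rng=rng)
        clean, report = reject_trials(dirty)
        rejected = set(report.loc[report.rejected, "trial"])
        assert rejected == set(int(i) for i in ids)
        assert clean.n_trials == dirty.n_trials - len(ids)

    def test_full_threshold_rejects_nothing(self, small_trialset):
        _, report = reject_trials(small_trialset, threshold=1.0)
        assert not report.rejected.any()

    def test_behavioral_flags_respected(self, small_trialset):
        flags = np.zeros(small_trialset.n_trials, dtype=bool)
        flags[4] = True
        _, report = reject_trials(small_trialset, behavioral_flags=flags)
        assert report.loc[4, "rejected"]
        assert report.loc[4, "reason"] == "behavioral"


class TestChannelAveraging:
    def test_identical_channels_pass_through(self, rng):
        x = rng.normal(size=200)
        out = average_hemisphere_channels(np.stack([x, x, x, x]), [0, 0, 1, 1])
        assert np.allclose(out[0], x) and np.allclose(out[1], x)

    def test_opposite_channels_cancel(self, rng):
        x = rng.normal(size=100)
        out = average_hemisphere_channels(np.stack([x, -x, x, x]), [0, 0, 1, 1])
        assert np.allclose(out[0], 0.0)

    def test_averaging_law(self, rng):
        s = np.sin(np.arange(5000) / 20.0)
        chans = np.stack([s + rng.normal(size=5000) for _ in range(4)])
        out = average_hemisphere_channels(
            np.vstack([chans, s[None, :]]), [0, 0, 0, 0, 1])
        rms = np.sqrt(((out[0] - s) ** 2).mean())
        assert rms == pytest.approx(0.5, rel=0.15)

    def test_noisy_channels_excluded(self, rng):
        x = rng.normal(size=100)
        out = average_hemisphere_channels(
            np.stack([x, 100 * x, x]), [0, 0, 1], noisy=[False, True, False])
        assert np.allclose(out[0], x)

    def test_empty_hemisphere_errors(self, rng):
        with pytest.raises(UnusableHemisphereError):
            average_hemisphere_channels(
                np.ones((2, 50)), [0, 0], noisy=[False, False])


class TestEpoch:
    def _events(self, onsets):
        return pd.DataFrame({"onset_s": onsets, "label": ["HN"] * len(onsets),
                             "withdrawal_ms": [220.0] * len(onsets)})

    def test_sample_conventions(self, rng):
        cont = rng.normal(size=(2, 20000))
        ts, skipped = epoch(cont, FS, self._events([10.0]))
        assert skipped == 0
        stim = ts.select(label="HN")
        ns = ts.select(label="NS")
        assert np.array_equal(stim.signals[0], cont[:, 10000:13000])
        assert np.array_equal(ns.signals[0], cont[:, 6000:9000])

    def test_event_count(self, rng):
        cont = rng.normal(size=(2, 300000))
        onsets = np.arange(10, 260, 5.0)
        ts, skipped = epoch(cont, FS, self._events(onsets))
        assert skipped == 0
        assert (ts.labels == "HN").sum() == 50
        assert (ts.labels == "NS").sum() == 50

    def test_out_of_bounds_skipped_with_warning(self, rng):
        cont = rng.normal(size=(2, 8000))
        with pytest.warns(UserWarning):
            ts, skipped = epoch(cont, FS, self._events([2.0]))
        assert skipped >= 1


class TestPipelineProperties:
    def test_zero_phase_preserves_template_extrema(self):
        tpl = make_ep_template(DEFAULT_EP_TEMPLATES["HN"], FS)
        filt = notch(bandpass(tpl, FS), FS)
        assert abs(int(np.argmax(filt)) - int(np.argmax(tpl))) <= 1
        assert abs(int(np.argmin(filt)) - int(np.argmin(tpl))) <= 1

    def test_preprocessing_near_idempotent(self, small_trialset):
        once, _ = preprocess_trialset(small_trialset, do_reject=False)
        twice, _ = preprocess_trialset(once, do_reject=False)
        rel = np.sqrt(((twice.signals - once.signals) ** 2).mean()) / once.signals.std()
        assert rel < 0.15  # band-edge re-attenuation only
        # and the scientifically load-bearing part: EP extrema do not move
        from painlfp.evoked import compute_ep
        for label in ("HN", "NN"):
            e1 = compute_ep(once, label=label)
            e2 = compute_ep(twice, label=label)
            assert abs(int(np.argmax(e1.mean)) - int(np.argmax(e2.mean))) <= 1

    def test_clean_synthetic_survival_rate(self):
        cfg = SimConfig(n_trials={"HN": 25, "NN": 25}, seed=13)  # default 2% artifacts
        ts = generate_trial_set(cfg)
        clean, report = preprocess_trialset(ts)
        assert clean.n_trials >= 0.98 * ts.n_trials - len(ts.meta["artifact_trials"])
        rejected = set(report.loc[report.rejected, "trial"])
        assert set(int(i) for i in ts.meta["artifact_trials"]) <= rejected
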