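"""Evoked-potential tests: averaging, P1/N1/P2 parametrization, samplewise
statistics calibration, and bilateral comparisons."""

import numpy as np
import pytest

from painlfp.datatypes import DEFAULT_EP_TEMPLATES, SimConfig, TrialSet
from painlfp.errors import InsufficientDataError
from painlfp.evoked import (
    EPWaveform,
    bilateral_ep_comparison,
    compare_classes_samplewise,
    compare_ep_params,
    compute_ep,
    extract_ep_params,
    extract_ep_params_per_trial,
    samplewise_vs_baseline,
)
from painlfp.simulate import generate_trial_set, make_ep_template

FS = 1000.0


def _trialset(signals, labels=None, onset=1000, fs=FS):
    """Wrap a (n, 2, T) array as a TrialSet with uniform onset."""
    n = signals.shape[0]
    labels = np.array(labels if labels is not None else ["HN"] * n)
    return TrialSet(signals, fs, np.full(n, onset), labels,
                    np.full(n, np.nan), np.zeros(n, dtype=int),
                    np.array(["s0"] * n))


def _stack(trials_1d):
    """(n, T) single-channel trials -> (n, 2, T) with equal hemispheres."""
    x = np.asarray(trials_1d)
    return np.stack([x, x], axis=1)


class TestComputeEP:
    def test_noiseless_average_equals_template(self):
        tpl = make_ep_template(DEFAULT_EP_TEMPLATES["HN"], FS, window_s=(1.0, 1.0))
        ts = _trialset(_stack([tpl] * 5))
        ep = compute_ep(ts)
        assert np.allclose(ep.mean, tpl)
        assert np.allclose(ep.sem, 0.0)

    def test_opposite_trials_average_to_zero(self, rng):
        x = rng.normal(size=600)
        ts = _trialset(_stack([x, -x]), onset=100)
        assert np.allclose(compute_ep(ts).mean, 0.0, atol=1e-12)

    def test_averaging_law(self, rng):
        tpl = make_ep_template(DEFAULT_EP_TEMPLATES["HN"], FS, window_s=(0.5, 1.0))
        n, sigma = 400, 1.0
        trials = tpl[None, :] + rng.normal(0, sigma, size=(n, tpl.size))
        ep = compute_ep(_trialset(_stack(trials), onset=500))
        rms = np.sqrt(((ep.mean - tpl) ** 2).mean())
        assert rms == pytest.approx(sigma / np.sqrt(n), rel=0.2)

    def test_linearity(self, rng):
        a = rng.normal(size=(6, 2, 300))
        b = rng.normal(size=(6, 2, 300))
        ep_sum = compute_ep(_trialset(2 * a + 3 * b, onset=10))
        ep_a = compute_ep(_trialset(a, onset=10))
        ep_b = compute_ep(_trialset(b, onset=10))
        assert np.allclose(ep_sum.mean, 2 * ep_a.mean + 3 * ep_b.mean)

    def test_insufficient_trials(self, rng):
        with pytest.raises(InsufficientDataError):
            compute_ep(_trialset(rng.normal(size=(1, 2, 100)), onset=10))


class TestExtractParams:
    def _ep_from_template(self, label):
        tpl = make_ep_template(DEFAULT_EP_TEMPLATES[label], FS)
        t = (np.arange(tpl.size) - 4000) / FS
        return EPWaveform(t, tpl, np.zeros_like(tpl), 10, label, "pooled")

    def test_hn_template_parameters(self):
        p = extract_ep_params(self._ep_from_template("HN"))
        assert p.p1_latency_ms == pytest.approx(92.0, abs=1.0)
        assert p.n1_latency_ms == pytest.approx(157.0, abs=1.0)
        assert p.p1_amp == pytest.approx(1.15, rel=0.02)
        assert p.n1_amp == pytest.approx(-1.17, rel=0.02)
        assert p.p2_present

    def test_nn_template_parameters(self):
        p = extract_ep_params(self._ep_from_template("NN"))
        assert p.p1_latency_ms == pytest.approx(61.0, abs=1.0)
        assert p.p1_amp == pytest.approx(0.21, rel=0.02)

    def test_flat_ep_has_no_components(self):
        t = (np.arange(3000) - 1000) / FS
        ep = EPWaveform(t, np.zeros(3000), np.zeros(3000), 5, "NS", "pooled")
        p = extract_ep_params(ep)
        assert p.p1_latency_ms is None and p.n1_latency_ms is None
        assert not p.p2_present


class TestSamplewise:
    def test_type_one_error_calibrated(self, rng):
        x = rng.normal(size=(200, 2, 1500))
        res = samplewise_vs_baseline(_trialset(x), baseline_s=(-1.0, 0.0))
        assert res.significant.mean() == pytest.approx(0.05, abs=0.02)

    def test_ep_lobes_flagged(self):
        tpl = make_ep_template(DEFAULT_EP_TEMPLATES["HN"], FS, window_s=(1.0, 1.0))
        rng = np.random.default_rng(0)
        trials = 5 * tpl[None, :] + 0.1 * rng.normal(size=(40, tpl.size))
        res = samplewise_vs_baseline(_trialset(_stack(trials)))
        t_ms = res.times * 1000.0
        lobe = (t_ms > 80) & (t_ms < 105)
        assert res.significant[lobe].all()

    def test_identical_values_not_flagged(self):
        x = np.tile(np.linspace(0, 1, 2000)[None, :], (10, 1)) * 0  # constant zero
        res = samplewise_vs_baseline(_trialset(_stack(x)))
        assert not res.significant.any()

    def test_class_comparison_calibration_and_symmetry(self, rng):
        a = _trialset(rng.normal(size=(80, 2, 800)), onset=100)
        b = _trialset(rng.normal(size=(80, 2, 800)), onset=100)
        res = compare_classes_samplewise(a, b)
        assert res.significant.mean() < 0.1
        res_swapped = compare_classes_samplewise(b, a)
        assert np.allclose(res.pvalue, res_swapped.pvalue)

    def test_disjoint_classes_all_flagged(self, rng):
        a = _trialset(rng.normal(size=(30, 2, 400)) + 10.0, onset=50)
        b = _trialset(rng.normal(size=(30, 2, 400)) - 10.0, onset=50)
        res = compare_classes_samplewise(a, b)
        assert res.significant.all()


class TestParamStatistics:
    def test_identical_classes_rarely_significant(self, rng):
        cols = ("p1_latency_ms", "n1_latency_ms", "p1_amp", "n1_amp")
        import pandas as pd

        hits = 0
        for _ in range(5):
            a = pd.DataFrame({c: rng.normal(size=60) for c in cols})
            b = pd.DataFrame({c: rng.normal(size=60) for c in cols})
            table = compare_ep_params(a, b)
            hits += int((table.pvalue < 0.05).any())
        assert hits <= 2

    def test_guided_per_trial_amplitudes_unbiased(self):
        cfg = SimConfig(n_trials={"HN": 150}, seed=5, artifact_rate=0.0,
                        session_gains=(1.0,), subject_effect_sd=0.0)
        ts = generate_trial_set(cfg)
        per = extract_ep_params_per_trial(ts, label="HN")
        # readout at the reference latency is unbiased up to smoothing loss
        assert per.p1_amp.mean() == pytest.approx(1.15, rel=0.25)
        assert per.p1_amp.std() == pytest.approx(1.0, rel=0.5)


class TestBilateral:
    def test_ipsi_gain_detected(self):
        cfg = SimConfig(n_trials={"HN": 150}, seed=9, artifact_rate=0.0)
        ts = generate_trial_set(cfg)  # default HN ipsi gain 1.3
        table = bilateral_ep_comparison(ts, label="HN")
        row = table.set_index("parameter").loc["|p1_amp|"]
        assert row.mean_ipsi > row.mean_contra
        assert row.pvalue < 0.05

    def test_identical_hemispheres_p_one(self):
        tpl = make_ep_template(DEFAULT_EP_TEMPLATES["HN"], FS, window_s=(1.0, 1.0))
        rng = np.random.default_rng(2)
        trials = tpl[None, :] + 0.2 * rng.normal(size=(20, tpl.size))
        table = bilateral_ep_comparison(_trialset(_stack(trials)))
        assert np.allclose(table.pvalue, 1.0)
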