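"""Synthetic bilateral-LFP trial generator.

Each trial is built from band-segmented 1/f^alpha Gaussian background noise
(spectrally shaped, exactly seedable), a class-specific evoked-potential
template, post-stimulus per-band gain modulation, and amplitude mixing of a
common source between the hemispheres (optionally with a post-stimulus
coupling dip).  The generator records its own ground truth (templates,
coupling traces, artifact trial ids) in ``TrialSet.meta`` so every
downstream stage has a recovery oracle.

Reproducibility: one root ``SeedSequence`` per trial set; each trial draws
from a counter-keyed child stream, so changing the trial count never
reshuffles earlier trials.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    BANDS,
    DEFAULT_BAND_MODULATION,
    DEFAULT_EP_TEMPLATES,
    BandModulationSpec,
    CouplingSpec,
    EPTemplateSpec,
    SimConfig,
    TrialSet,
)
from .errors import InvalidArgumentError, TemplateInfeasibleError
from .preprocess import bandpass

# Spectral segments partitioning the 3-350 Hz recording band: the five
# canonical sub-bands plus the flanks below theta and above high-gamma.
SEGMENTS: tuple[tuple[str, float, float], ...] = (
    ("sub_theta", 3.0, 4.0),
    *BANDS,
    ("supra_gamma", 120.0, 350.0),
)


# ---------------------------------------------------------------------------
# Background noise
# ---------------------------------------------------------------------------

def _shaping(n_samples: int, fs: float, alpha: float, sd: float,
             f_lo: float, f_hi: float) -> np.ndarray:
    """rfft-bin amplitude shaping for 1/f^alpha noise band-limited to
    [f_lo, f_hi], normalized so the expected signal variance is sd**2."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    shape[band] = freqs[band] ** (-alpha / 2.0)
    # E[var] for white N(0,1) input filtered by |S|: (1/n) * sum over the
    # full (two-sided) spectrum of S^2.
    full = shape ** 2
    weight = np.full_like(full, 2.0)
    weight[0] = 1.0
    if n_samples % 2 == 0:
        weight[-1] = 1.0
    evar = float((full * weight).sum()) / n_samples
    if evar > 0:
        shape *= sd / np.sqrt(evar)
    return shape


def _shaped_noise(shape: np.ndarray, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(n_samples)
    return np.fft.irfft(np.fft.rfft(w) * shape, n=n_samples)


def generate_background(n_samples: int, fs: float, alpha: float = 1.0, sd: float = 1.0,
                        rng: np.random.Generator | None = None,
                        f_lo: float = 3.0, f_hi: float = 350.0) -> np.ndarray:
    """Zero-mean Gaussian noise with PSD proportional to 1/f^alpha over
    [f_lo, f_hi] Hz and expected variance sd**2."""
    if n_samples <= 0:
        raise InvalidArgumentError("n_samples must be positive")
    if sd < 0:
        raise InvalidArgumentError("sd must be >= 0")
    if alpha < 0:
        raise InvalidArgumentError("alpha must be >= 0")
    if sd == 0.0:
        return np.zeros(n_samples)
    if rng is None:
        rng = np.random.default_rng()
    x = _shaped_noise(_shaping(n_samples, fs, alpha, sd, f_lo, f_hi), n_samples, rng)
    return x - x.mean()


# ---------------------------------------------------------------------------
# Evoked-potential template
# ---------------------------------------------------------------------------

def _lobes(centers_ms: np.ndarray, amps: np.ndarray, widths_ms: np.ndarray,
           t_ms: np.ndarray) -> np.ndarray:
    sigmas = widths_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sigma
    out = np.zeros_like(t_ms)
    for c, a, s in zip(centers_ms, amps, sigmas):
        out += a * np.exp(-0.5 * ((t_ms - c) / s) ** 2)
    return out


def make_ep_template(spec: EPTemplateSpec, fs: float,
                     window_s: tuple[float, float] = (4.0, 5.0),
                     band_limit: tuple[float, float] | None = (3.0, 350.0),
                     max_iter: int = 12) -> np.ndarray:
    """Render a template spec into a sampled waveform on the epoch grid.

    The waveform is a sum of Gaussian lobes, optionally band-limited to the
    recording band so that re-filtering in preprocessing leaves it (and its
    extrema) essentially unchanged.  Lobe centers and amplitudes are
    adjusted by fixed-point iteration until each component's extremum sits
    at the spec latency (nearest sample) with the spec amplitude; if the
    components overlap too strongly for that to converge, a
    ``TemplateInfeasibleError`` is raised.
    """
    pre, post = window_s
    n = int(round((pre + post) * fs))
    onset = int(round(pre * fs))
    t_ms = (np.arange(n) - onset) / fs * 1000.0
    comps = spec.components
    if not comps:
        return np.zeros(n)

    target_lat = np.array([c.latency_ms for c in comps])
    target_amp = np.array([c.signed_amplitude for c in comps])
    widths = np.array([c.width_ms for c in comps])
    centers = target_lat.copy()
    amps = target_amp.copy()
    half_win = np.maximum(1.25 * widths, 15.0)

    wave = None
    for _ in range(max_iter):
        raw = _lobes(centers, amps, widths, t_ms)
        wave = bandpass(raw, fs, band_limit[0], band_limit[1]) if band_limit else raw
        ok = True
        for k in range(len(comps)):
            sel = (t_ms >= target_lat[k] - half_win[k]) & (t_ms <= target_lat[k] + half_win[k])
            seg = wave[sel]
            idx = int(np.argmax(seg)) if target_amp[k] > 0 else int(np.argmin(seg))
            got_lat = t_ms[sel][idx]
            got_val = seg[idx]
            if got_val * target_amp[k] <= 0:
                raise TemplateInfeasibleError(
                    f"component {k} extremum has the wrong sign after shaping"
                )
            lat_err = target_lat[k] - got_lat
            if abs(lat_err) > 1000.0 / fs / 2.0 + 1e-9:
                ok = False
            if abs(got_val - target_amp[k]) > 1e-3 * abs(target_amp[k]):
                ok = False
            centers[k] += 0.9 * lat_err
            amps[k] *= target_amp[k] / got_val
        if ok:
            return wave
    # final verification after the last update
    raw = _lobes(centers, amps, widths, t_ms)
    wave = bandpass(raw, fs, band_limit[0], band_limit[1]) if band_limit else raw
    for k in range(len(comps)):
        sel = (t_ms >= target_lat[k] - half_win[k]) & (t_ms <= target_lat[k] + half_win[k])
        seg = wave[sel]
        idx = int(np.argmax(seg)) if target_amp[k] > 0 else int(np.argmin(seg))
        if (abs(t_ms[sel][idx] - target_lat[k]) > 1000.0 / fs + 1e-9
                or abs(seg[idx] - target_amp[k]) > 0.01 * abs(target_amp[k])):
            raise TemplateInfeasibleError(
                "overlapping components shift extrema beyond tolerance"
            )
    return wave


# ---------------------------------------------------------------------------
# Trial-set generation
# ---------------------------------------------------------------------------

def _gain_profile(mod, t: np.ndarray) -> np.ndarray:
    """Band gain g(t): 1 pre-stimulus, early_gain on the early window, then
    late_gain relaxing linearly to 1 at recovery_time_s."""
    g = np.ones_like(t)
    early = (t >= 0) & (t < mod.early_window_s)
    g[early] = mod.early_gain
    late = (t >= mod.early_window_s) & (t < mod.recovery_time_s)
    if mod.recovery_time_s > mod.early_window_s:
        frac = (t[late] - mod.early_window_s) / (mod.recovery_time_s - mod.early_window_s)
        g[late] = mod.late_gain + (1.0 - mod.late_gain) * frac
    return g


def generate_trial_set(config: SimConfig,
                       ep_templates: dict[str, EPTemplateSpec] | None = None,
                       band_modulation: dict[str, BandModulationSpec] | None = None,
                       coupling: CouplingSpec | None = None) -> TrialSet:
    """Generate an epoched bilateral TrialSet with the configured structure.

    Per trial and hemisphere the signal is session_gain * (mixed background
    + subject_effect * hemisphere-scaled EP template), where the background
    is the sum over spectral segments of gain-modulated shared/independent
    noise mixtures.  HN trials carry withdrawal latencies; artifacts are
    injected afterwards at ``config.artifact_rate``.
    """
    if ep_templates is None:
        ep_templates = dict(DEFAULT_EP_TEMPLATES)
    if band_modulation is None:
        band_modulation = dict(DEFAULT_BAND_MODULATION)
    if coupling is None:
        coupling = CouplingSpec()

    fs, n = config.fs, config.n_samples
    onset = config.onset_idx
    t = (np.arange(n) - onset) / fs

    shaping = _shaping(n, fs, config.noise_exponent, config.noise_sd,
                       config.noise_band[0], config.noise_band[1])
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    seg_shapes = []
    for _, lo, hi in SEGMENTS:
        m = (freqs >= lo) & (freqs < hi)
        seg_shapes.append(np.where(m, shaping, 0.0))

    classes = [c for c in ("HN", "NN", "NS") if config.n_trials.get(c, 0) > 0]
    templates = {
        c: make_ep_template(ep_templates[c], fs, config.window_s) for c in classes
    }
    band_names = {b[0] for b in BANDS}
    gain_profiles = {
        c: [
            _gain_profile(band_modulation.get(c, BandModulationSpec()).profile(name), t)
            if name in band_names
            else np.ones_like(t)
            for name, _, _ in SEGMENTS
        ]
        for c in classes
    }
    coupling_traces = {c: coupling.trace(t, c) for c in classes}

    meta_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10 ** 6,)))
    subjects = [f"rat{i + 1}" for i in range(config.n_subjects)]
    subject_effect = {
        s: 1.0 + config.subject_effect_sd * meta_rng.standard_normal() for s in subjects
    }

    total = sum(config.n_trials[c] for c in classes)
    signals = np.empty((total, 2, n))
    labels = np.empty(total, dtype="U2")
    withdrawal = np.full(total, np.nan)
    session = np.empty(total, dtype=object)
    subject = np.empty(total, dtype=object)

    n_sessions = max(len(config.session_gains), 1)
    gains = config.session_gains if config.session_gains else (1.0,)

    idx = 0
    for label in classes:
        tpl = templates[label]
        s_ipsi, s_contra = ep_templates[label].hemisphere_scales
        c_t = coupling_traces[label]
        norm = np.sqrt(c_t ** 2 + (1.0 - c_t) ** 2)
        profs = gain_profiles[label]
        for _ in range(config.n_trials[label]):
            rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(idx,)))
            subj = subjects[idx % config.n_subjects]
            sess_i = (idx // config.n_subjects) % n_sessions
            bg = np.zeros((2, n))
            for seg_shape, g in zip(seg_shapes, profs):
                shared = _shaped_noise(seg_shape, n, rng)
                u0 = _shaped_noise(seg_shape, n, rng)
                u1 = _shaped_noise(seg_shape, n, rng)
                mix0 = (c_t * shared + (1.0 - c_t) * u0) / norm
                mix1 = (c_t * shared + (1.0 - c_t) * u1) / norm
                bg[0] += g * mix0
                bg[1] += g * mix1
            eff = subject_effect[subj]
            sig = bg
            sig[0] += eff * s_ipsi * tpl
            sig[1] += eff * s_contra * tpl
            signals[idx] = gains[sess_i] * sig
            labels[idx] = label
            if label == "HN":
                withdrawal[idx] = max(
                    rng.normal(config.withdrawal_mean_ms, config.withdrawal_sd_ms), 0.0
                )
            session[idx] = f"{subj}_s{sess_i}"
            subject[idx] = subj
            idx += 1

    ts = TrialSet(
        signals,
        fs,
        np.full(total, onset, dtype=int),
        labels,
        withdrawal,
        np.array(session, dtype="U16"),
        np.array(subject, dtype="U16"),
        meta={
            "seed": config.seed,
            "config": config,
            "templates": templates,
            "template_specs": {c: ep_templates[c] for c in classes},
            "coupling": coupling_traces,
            "coupling_spec": coupling,
            "subject_effect": subject_effect,
            "artifact_trials": np.array([], dtype=int),
        },
    )
    if config.artifact_rate > 0:
        art_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10 ** 6 + 1,)))
        ts, ids = inject_artifacts(ts, config.artifact_rate, config.artifact_magnitude, art_rng)
        ts.meta["artifact_trials"] = ids
    return ts


def inject_artifacts(trial_set: TrialSet, rate: float, magnitude: float = 20.0,
                     rng: np.random.Generator | None = None,
                     fraction_of_epoch: float = 0.18) -> tuple[TrialSet, np.ndarray]:
    """Add contiguous high-amplitude motion-artifact bursts to
    floor(rate * n_trials) trials chosen without replacement.

    The burst is an oscillatory excursion (Gaussian noise scaled to
    ``magnitude`` times the trial's standard deviation) spanning
    ``fraction_of_epoch`` of the samples, comfortably above the 10%
    outlier-fraction rejection threshold.  Returns the new TrialSet and
    the affected trial ids.
    """
    if not 0.0 <= rate <= 1.0:
        raise InvalidArgumentError("rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    n_affect = int(np.floor(rate * trial_set.n_trials))
    out = trial_set.copy()
    if n_affect == 0:
        out.meta["artifact_trials"] = np.array([], dtype=int)
        return out, np.array([], dtype=int)
    ids = np.sort(rng.choice(trial_set.n_trials, size=n_affect, replace=False))
    ns = trial_set.n_samples
    seg = max(int(np.ceil(fraction_of_epoch * ns)), 1)
    for i in ids:
        start = int(rng.integers(0, ns - seg + 1))
        hemi = int(rng.integers(0, 2))
        sd = out.signals[i, hemi].std() or 1.0
        # oscillatory Gaussian burst: heavy spread keeps the Grubbs statistic
        # above its critical value throughout the iterative removal
        burst = magnitude * sd * rng.standard_normal(seg)
        out.signals[i, hemi, start:start + seg] += burst
    out.meta["artifact_trials"] = ids
    return out, ids
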