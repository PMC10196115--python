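"""Core domain types shared across the pipeline.

The central currency is :class:`TrialSet`: epoched bilateral LFP trials
(trial x hemisphere x sample) together with class labels (HN: high-intensity
noxious, NN: non-noxious, NS: no stimulation), stimulus-onset indices,
behavioral withdrawal latencies, and session/subject metadata.

Hemisphere axis convention: index 0 is the hemisphere ipsilateral to the
stimulated (left) hind paw, index 1 contralateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError

VALID_LABELS = ("HN", "NN", "NS")
HEMISPHERES = ("ipsi", "contra")

#: Canonical LFP sub-bands (name, lower edge Hz, upper edge Hz), ordered and
#: contiguous: theta, alpha, beta, low-gamma, high-gamma.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
    ("low_gamma", 30.0, 80.0),
    ("high_gamma", 80.0, 120.0),
)
BAND_NAMES = tuple(b[0] for b in BANDS)


# ---------------------------------------------------------------------------
# Evoked-potential templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EPComponent:
    """One monophasic lobe of an evoked-potential template.

    ``amplitude`` is the unsigned magnitude in normalized z-units; the sign
    comes from ``polarity`` ('+' or '-').  ``width_ms`` is the full width at
    half maximum of the Gaussian lobe.
    """

    polarity: str
    latency_ms: float
    amplitude: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise InvalidArgumentError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if self.width_ms <= 0:
            raise InvalidArgumentError("component width must be > 0")
        if self.amplitude < 0:
            raise InvalidArgumentError("amplitude is unsigned; use polarity for sign")

    @property
    def signed_amplitude(self) -> float:
        return self.amplitude if self.polarity == "+" else -self.amplitude


@dataclass(frozen=True)
class EPTemplateSpec:
    """Evoked-potential template: an ordered sequence of lobes plus the
    ipsi/contra amplitude ratio.

    ``ipsi_gain`` >= 1 is the ipsilateral : contralateral amplitude ratio.
    Component amplitudes are interpreted as the *bilateral mean*: the
    generator scales the ipsilateral copy by ``2g/(1+g)`` and the
    contralateral copy by ``2/(1+g)`` so that the hemisphere-pooled evoked
    potential keeps the spec amplitudes while preserving the ratio ``g``.
    """

    components: tuple[EPComponent, ...] = ()
    ipsi_gain: float = 1.0

    def __post_init__(self) -> None:
        lats = [c.latency_ms for c in self.components]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise InvalidArgumentError("component latencies must be strictly increasing")
        if self.ipsi_gain < 1.0:
            raise InvalidArgumentError("ipsi_gain must be >= 1")

    @property
    def hemisphere_scales(self) -> tuple[float, float]:
        g = self.ipsi_gain
        return (2.0 * g / (1.0 + g), 2.0 / (1.0 + g))


def _ep(components: Sequence[tuple[str, float, float, float]], ipsi_gain: float = 1.0) -> EPTemplateSpec:
    return EPTemplateSpec(tuple(EPComponent(*c) for c in components), ipsi_gain)


#: Default templates.  HN/NN P1 and N1 latencies and amplitudes follow the
#: reported rat-ACC mechano-nociceptive evoked potentials (P1 at 92 ms /
#: 1.15 z for HN, 61 ms / 0.21 z for NN; N1 at 157 ms, -1.17 / -0.18 z).
#: HN additionally carries a small P2 lobe; NS has no evoked response.
DEFAULT_EP_TEMPLATES: Mapping[str, EPTemplateSpec] = {
    "HN": _ep(
        [("+", 92.0, 1.15, 25.0), ("-", 157.0, 1.17, 25.0), ("+", 235.0, 0.45, 40.0)],
        ipsi_gain=1.3,
    ),
    "NN": _ep([("+", 61.0, 0.21, 25.0), ("-", 157.0, 0.18, 25.0)], ipsi_gain=1.0),
    "NS": _ep([]),
}


# ---------------------------------------------------------------------------
# Band-power modulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandModulation:
    """Post-stimulus gain profile for one frequency band.

    The band's amplitude is multiplied by ``early_gain`` on
    [0, ``early_window_s``] s after onset, then by ``late_gain`` at the start
    of the late interval, relaxing linearly back to 1 at ``recovery_time_s``.
    """

    early_gain: float = 1.0
    late_gain: float = 1.0
    recovery_time_s: float = 4.0
    early_window_s: float = 0.5

    def __post_init__(self) -> None:
        if self.early_gain <= 0 or self.late_gain <= 0:
            raise InvalidArgumentError("band gains must be > 0")
        if self.recovery_time_s < self.early_window_s:
            raise InvalidArgumentError("recovery_time_s must be >= early_window_s")


@dataclass(frozen=True)
class BandModulationSpec:
    """Per-band modulation profiles keyed by band name."""

    bands: Mapping[str, BandModulation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.bands) - set(BAND_NAMES)
        if unknown:
            raise InvalidArgumentError(f"unknown band names: {sorted(unknown)}")

    def profile(self, name: str) -> BandModulation:
        return self.bands.get(name, BandModulation())


#: Default class-specific modulation: after a noxious stimulus every band
#: transiently gains power in the first 500 ms; afterwards theta/alpha/beta
#: drop below baseline while the gamma bands stay elevated, with linear
#: recovery by 4 s.  The non-noxious profile has the same shape at smaller
#: amplitude; no-stimulation trials are unmodulated.
DEFAULT_BAND_MODULATION: Mapping[str, BandModulationSpec] = {
    "HN": BandModulationSpec(
        {
            "theta": BandModulation(1.5, 0.6, 4.0),
            "alpha": BandModulation(1.5, 0.6, 4.0),
            "beta": BandModulation(1.5, 0.6, 4.0),
            "low_gamma": BandModulation(2.0, 1.4, 4.0),
            "high_gamma": BandModulation(2.0, 1.4, 4.0),
        }
    ),
    "NN": BandModulationSpec(
        {
            "theta": BandModulation(1.2, 0.85, 2.5),
            "alpha": BandModulation(1.2, 0.85, 2.5),
            "beta": BandModulation(1.2, 0.85, 2.5),
            "low_gamma": BandModulation(1.4, 1.15, 2.5),
            "high_gamma": BandModulation(1.4, 1.15, 2.5),
        }
    ),
    "NS": BandModulationSpec({}),
}


# ---------------------------------------------------------------------------
# Interhemispheric coupling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingSpec:
    """Amplitude mixing of a common source between the hemispheres.

    Each hemisphere is ``c(t)*shared + (1-c(t))*independent`` (variance
    renormalized), so ``shared_fraction`` c controls baseline correlation and
    phase locking.  After a stimulus, c drops by ``post_stim_dip_depth *
    class_scale[label]`` at ``dip_onset_s`` and relaxes linearly back over
    ``dip_duration_s`` - the post-stimulus desynchronization dip.
    """

    shared_fraction: float = 0.7
    baseline_plv_target: float | None = None
    post_stim_dip_depth: float = 0.35
    dip_duration_s: float = 3.5
    dip_onset_s: float = 0.5
    class_scale: Mapping[str, float] = field(
        default_factory=lambda: {"HN": 1.0, "NN": 0.25, "NS": 0.0}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise InvalidArgumentError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.post_stim_dip_depth <= 1.0:
            raise InvalidArgumentError("post_stim_dip_depth must be in [0, 1]")
        if self.baseline_plv_target is not None and not 0.0 <= self.baseline_plv_target <= 1.0:
            raise InvalidArgumentError("baseline_plv_target must be in [0, 1]")
        if self.dip_duration_s < 0:
            raise InvalidArgumentError("dip_duration_s must be >= 0")

    def trace(self, t: np.ndarray, label: str) -> np.ndarray:
        """Shared-fraction c(t) for one trial of class ``label``."""
        c = np.full(t.shape, self.shared_fraction, dtype=float)
        depth = self.post_stim_dip_depth * float(self.class_scale.get(label, 0.0))
        if depth <= 0 or self.dip_duration_s == 0:
            return c
        t0, dur = self.dip_onset_s, self.dip_duration_s
        dip = self.shared_fraction * depth
        in_dip = (t >= t0) & (t < t0 + dur)
        c[in_dip] -= dip * (1.0 - (t[in_dip] - t0) / dur)
        return np.clip(c, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Full configuration of the synthetic bilateral-LFP generator.

    ``window_s = (pre, post)`` gives the epoch extent around stimulus onset
    in seconds; at ``fs`` = 1000 Hz the default (4, 5) yields 9000-sample
    trials with onset at index 4000.  ``noise_sd`` is the background
    standard deviation in the same normalized z-units as the evoked
    templates (sessions are z-scored, so 1.0 is the faithful scale).
    """

    fs: float = 1000.0
    n_trials: Mapping[str, int] = field(
        default_factory=lambda: {"HN": 200, "NN": 200, "NS": 400}
    )
    window_s: tuple[float, float] = (4.0, 5.0)
    noise_exponent: float = 1.0
    noise_sd: float = 1.0
    noise_band: tuple[float, float] = (3.0, 350.0)
    artifact_rate: float = 0.02
    artifact_magnitude: float = 20.0
    withdrawal_mean_ms: float = 225.0
    withdrawal_sd_ms: float = 10.0
    session_gains: tuple[float, ...] = (1.0, 1.15, 0.9, 1.05)
    n_subjects: int = 4
    subject_effect_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.noise_band[1]:
            raise InvalidArgumentError("fs must exceed twice the highest band edge")
        if any(n < 1 for n in self.n_trials.values()):
            raise InvalidArgumentError("need >= 1 trial per requested class")
        unknown = set(self.n_trials) - set(VALID_LABELS)
        if unknown:
            raise InvalidArgumentError(f"unknown trial classes: {sorted(unknown)}")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise InvalidArgumentError("artifact_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.noise_exponent < 0:
            raise InvalidArgumentError("noise exponent must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round((self.window_s[0] + self.window_s[1]) * self.fs))

    @property
    def onset_idx(self) -> int:
        return int(round(self.window_s[0] * self.fs))


def paper_scale_config(**overrides) -> SimConfig:
    """Study-scale preset: 657 HN / 533 NN / 1190 NS trials."""
    kw = dict(n_trials={"HN": 657, "NN": 533, "NS": 1190}, n_subjects=7)
    kw.update(overrides)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# Trial container
# ---------------------------------------------------------------------------

@dataclass
class TrialSet:
    """Epoched bilateral LFP trials.

    ``signals`` has shape (n_trials, 2, n_samples) with hemisphere axis
    ordered (ipsi, contra).  ``onset_idx`` is the stimulus-onset sample of
    each trial (0-based); ``withdrawal_ms`` is NaN for non-HN trials.
    ``meta`` may carry generator ground truth ('templates', 'coupling',
    'artifact_trials', ...) used as recovery oracles in testing.
    """

    signals: np.ndarray
    fs: float
    onset_idx: np.ndarray
    labels: np.ndarray
    withdrawal_ms: np.ndarray
    session: np.ndarray
    subject: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 3 or self.signals.shape[1] != 2:
            raise InvalidArgumentError("signals must have shape (n_trials, 2, n_samples)")
        if not np.all(np.isfinite(self.signals)):
            raise InvalidArgumentError("signals must be finite")
        n = self.signals.shape[0]
        self.onset_idx = np.asarray(self.onset_idx, dtype=int)
        self.labels = np.asarray(self.labels, dtype="U2")
        self.withdrawal_ms = np.asarray(self.withdrawal_ms, dtype=float)
        self.session = np.asarray(self.session)
        self.subject = np.asarray(self.subject)
        for name, arr in (
            ("onset_idx", self.onset_idx),
            ("labels", self.labels),
            ("withdrawal_ms", self.withdrawal_ms),
            ("session", self.session),
            ("subject", self.subject),
        ):
            if len(arr) != n:
                raise InvalidArgumentError(f"{name} length {len(arr)} != n_trials {n}")
        if not set(np.unique(self.labels)) <= set(VALID_LABELS):
            raise InvalidArgumentError(f"labels must be a subset of {VALID_LABELS}")
        if np.any(self.onset_idx < 0) or np.any(self.onset_idx >= self.signals.shape[2]):
            raise InvalidArgumentError("onset indices must lie inside the sample range")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    def times(self) -> np.ndarray:
        """Time axis in seconds relative to onset (requires a uniform onset)."""
        if len(np.unique(self.onset_idx)) > 1:
            raise InvalidArgumentError("trials have non-uniform onsets; no common time axis")
        on = int(self.onset_idx[0]) if self.n_trials else 0
        return (np.arange(self.n_samples) - on) / self.fs

    def select(self, label: str | None = None, mask: np.ndarray | None = None) -> "TrialSet":
        """Subset by class label and/or boolean mask (meta is carried over)."""
        keep = np.ones(self.n_trials, dtype=bool)
        if label is not None:
            keep &= self.labels == label
        if mask is not None:
            keep &= np.asarray(mask, dtype=bool)
        return TrialSet(
            self.signals[keep],
            self.fs,
            self.onset_idx[keep],
            self.labels[keep],
            self.withdrawal_ms[keep],
            self.session[keep],
            self.subject[keep],
            dict(self.meta),
        )

    def copy(self) -> "TrialSet":
        return TrialSet(
            self.signals.copy(),
            self.fs,
            self.onset_idx.copy(),
            self.labels.copy(),
            self.withdrawal_ms.copy(),
            self.session.copy(),
            self.subject.copy(),
            dict(self.meta),
        )

    def with_signals(self, signals: np.ndarray) -> "TrialSet":
        return replace(self.copy(), signals=np.asarray(signals, dtype=float))
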