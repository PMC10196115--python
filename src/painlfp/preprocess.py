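"""Raw-signal conditioning: band-pass/notch filtering, session z-scoring,
Grubbs-based artifact-trial rejection, hemisphere channel averaging, and
epoching.

All filters are applied zero-phase (forward-backward), so the effective
attenuation is the squared single-pass Butterworth magnitude and evoked
component latencies are not biased.  Sample indexing is 0-based with
half-open [start, stop) ranges; time 0 is the stimulus onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal as sg
import scipy.stats as st

from .datatypes import TrialSet
from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidArgumentError,
    UnusableHemisphereError,
)

DEFAULT_WINDOWS = {"NS": (-4.0, -1.0), "stim": (0.0, 3.0)}


@dataclass(frozen=True)
class NormalizationParams:
    """Session mean and standard deviation used for z-scoring (Eq. z = (x - mean)/sd)."""

    mean: float
    sd: float


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass(signal: np.ndarray, fs: float, lo: float = 3.0, hi: float = 350.0,
             order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 3-350 Hz, order 4)."""
    if not 0 < lo < hi:
        raise InvalidArgumentError("need 0 < lo < hi")
    if hi >= fs / 2:
        raise InvalidArgumentError("upper edge must be below the Nyquist frequency")
    if order < 1:
        raise InvalidArgumentError("order must be >= 1")
    sos = sg.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sg.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=axis)


def notch(signal: np.ndarray, fs: float, mains: float = 50.0,
          n_harmonics: int | None = None, q: float = 30.0,
          upper: float = 350.0, axis: int = -1) -> np.ndarray:
    """Zero-phase IIR notch at the mains frequency and its harmonics.

    Harmonics are notched up to min(``upper``, Nyquist); with 50 Hz mains and
    the default 350 Hz cap that is 50, 100, ..., 350 Hz.
    """
    if mains >= fs / 2:
        raise InvalidArgumentError("mains frequency must be below Nyquist")
    top = min(upper, fs / 2 * 0.999)
    if n_harmonics is None:
        n_harmonics = int(top // mains)
    out = np.asarray(signal, dtype=float)
    for h in range(1, n_harmonics + 1):
        f0 = mains * h
        if f0 > top:
            break
        b, a = sg.iirnotch(f0, q, fs=fs)
        out = sg.filtfilt(b, a, out, axis=axis)
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def zscore(signal: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Z-score a 1-D signal: z = (x - mean) / sd with the sample (n-1) sd."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 2:
        raise InsufficientDataError("z-scoring needs at least 2 samples")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("constant signal has zero standard deviation")
    return (x - mean) / sd, NormalizationParams(mean, sd)


def zscore_session(trial_set: TrialSet) -> tuple[TrialSet, pd.DataFrame]:
    """Z-score each hemisphere channel per recording session.

    Statistics are pooled over all samples of all trials belonging to the
    same session, per hemisphere, mirroring normalization of a continuous
    session recording.  Returns the normalized set and a parameter table.
    """
    out = trial_set.copy()
    rows = []
    for sess in np.unique(trial_set.session):
        m = trial_set.session == sess
        for h in range(2):
            x = trial_set.signals[m, h, :]
            mean = float(x.mean())
            sd = float(x.std(ddof=1))
            if sd == 0.0:
                raise DegenerateInputError(f"session {sess} hemisphere {h} is constant")
            out.signals[m, h, :] = (x - mean) / sd
            rows.append({"session": sess, "hemisphere": h, "mean": mean, "sd": sd})
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Grubbs outlier detection and trial rejection
# ---------------------------------------------------------------------------

def _grubbs_critical(n: int, alpha: float) -> float:
    t = st.t.ppf(alpha / (2.0 * n), n - 2)
    t2 = t * t
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_outlier_mask(samples: np.ndarray, alpha: float = 0.05,
                        max_outliers: int | None = None) -> np.ndarray:
    """Iterative two-sided Grubbs test; flags one extreme sample per
    iteration while G = max|x - mean|/sd exceeds the critical value.

    Returns a boolean mask of flagged samples.  ``max_outliers`` caps the
    number of iterations (useful when only an outlier *fraction* threshold
    matters).
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if n < 7:
        raise InsufficientDataError("Grubbs test needs at least 7 samples")
    if max_outliers is None:
        max_outliers = n - 5
    mask = np.zeros(n, dtype=bool)
    # running sums for O(1) mean/sd updates
    s1 = float(x.sum())
    s2 = float((x * x).sum())
    n_rem = n
    for _ in range(max_outliers):
        mean = s1 / n_rem
        var = (s2 - n_rem * mean * mean) / (n_rem - 1)
        sd = np.sqrt(max(var, 0.0))
        if sd == 0.0:
            break
        dev = np.abs(x - mean)
        dev[mask] = -1.0  # flagged samples are out of the pool
        idx = int(np.argmax(dev))
        g = dev[idx] / sd
        if g <= _grubbs_critical(n_rem, alpha):
            break
        mask[idx] = True
        s1 -= x[idx]
        s2 -= x[idx] * x[idx]
        n_rem -= 1
        if n_rem < 7:
            break
    return mask


def reject_trials(trial_set: TrialSet, threshold: float = 0.10,
                  behavioral_flags: np.ndarray | None = None,
                  alpha: float = 0.05) -> tuple[TrialSet, pd.DataFrame]:
    """Drop trials whose Grubbs outlier-sample fraction exceeds ``threshold``
    in either hemisphere, plus behaviorally flagged (defective) trials.

    Returns the surviving trials and a report covering every input trial
    with columns trial, outlier_fraction, rejected, reason.  The Grubbs
    iteration per trial is capped at twice the threshold fraction: the
    reject/keep decision only needs to know whether the fraction crosses
    the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise InvalidArgumentError("threshold must be in (0, 1]")
    n = trial_set.n_trials
    ns = trial_set.n_samples
    cap = min(ns - 7, int(np.ceil(2.0 * threshold * ns)) + 1)
    if behavioral_flags is None:
        behavioral_flags = np.zeros(n, dtype=bool)
    behavioral_flags = np.asarray(behavioral_flags, dtype=bool)
    fracs = np.zeros(n)
    for i in range(n):
        worst = 0.0
        for h in range(2):
            m = grubbs_outlier_mask(trial_set.signals[i, h], alpha=alpha, max_outliers=cap)
            worst = max(worst, m.mean())
        fracs[i] = worst
    grubbs_rej = fracs > threshold
    rejected = grubbs_rej | behavioral_flags
    reason = np.where(behavioral_flags, "behavioral", np.where(grubbs_rej, "grubbs", ""))
    report = pd.DataFrame(
        {
            "trial": np.arange(n),
            "outlier_fraction": fracs,
            "rejected": rejected,
            "reason": reason,
        }
    )
    return trial_set.select(mask=~rejected), report


# ---------------------------------------------------------------------------
# Channel averaging and epoching
# ---------------------------------------------------------------------------

def average_hemisphere_channels(channels: np.ndarray, hemisphere_of: np.ndarray,
                                noisy: np.ndarray | None = None) -> np.ndarray:
    """Average retained channels per hemisphere into one bilateral signal.

    ``channels`` is (n_channels, n_samples); ``hemisphere_of`` maps each
    channel to 0 (ipsi) or 1 (contra); ``noisy`` marks channels excluded
    from the average.  Returns a (2, n_samples) array.
    """
    channels = np.asarray(channels, dtype=float)
    hemisphere_of = np.asarray(hemisphere_of)
    if noisy is None:
        noisy = np.zeros(len(channels), dtype=bool)
    noisy = np.asarray(noisy, dtype=bool)
    out = np.empty((2, channels.shape[1]))
    for h in range(2):
        keep = (hemisphere_of == h) & ~noisy
        if not keep.any():
            raise UnusableHemisphereError(f"hemisphere {h} has no retained channels")
        out[h] = channels[keep].mean(axis=0)
    return out


def epoch(continuous: np.ndarray, fs: float, events: pd.DataFrame,
          windows: dict[str, tuple[float, float]] | None = None) -> tuple[TrialSet, int]:
    """Cut a continuous bilateral recording into epoched trials.

    ``events`` needs columns onset_s and label (HN/NN); optional
    withdrawal_ms, session, subject.  For every event a stimulus epoch is
    cut on ``windows['stim']`` and a no-stimulation epoch on
    ``windows['NS']`` (both relative to onset, half-open in samples).
    Events whose windows fall outside the recording are skipped with a
    warning; the skipped count is returned alongside the TrialSet.
    """
    if windows is None:
        windows = DEFAULT_WINDOWS
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2 or continuous.shape[0] != 2:
        raise InvalidArgumentError("continuous must be (2, n_samples)")
    lengths = {
        name: int(round((w[1] - w[0]) * fs)) for name, w in windows.items()
    }
    if len(set(lengths.values())) != 1:
        raise InvalidArgumentError("all epoch windows must have equal sample counts")
    n_total = continuous.shape[1]
    sig, labels, onsets, wdl, sess, subj = [], [], [], [], [], []
    skipped = 0
    for _, ev in events.iterrows():
        on = int(round(float(ev["onset_s"]) * fs))
        for name, (a, b) in windows.items():
            start, stop = on + int(round(a * fs)), on + int(round(b * fs))
            if start < 0 or stop > n_total:
                skipped += 1
                warnings.warn(f"event at {ev['onset_s']} s: window {name} outside recording; skipped")
                continue
            sig.append(continuous[:, start:stop])
            if name == "NS":
                labels.append("NS")
                onsets.append(0)
                wdl.append(np.nan)
            else:
                labels.append(str(ev["label"]))
                onsets.append(-int(round(a * fs)))
                wdl.append(float(ev.get("withdrawal_ms", np.nan)))
            sess.append(ev.get("session", 0))
            subj.append(ev.get("subject", "s0"))
    ts = TrialSet(
        np.stack(sig) if sig else np.empty((0, 2, list(lengths.values())[0])),
        fs,
        np.array(onsets, dtype=int),
        np.array(labels, dtype="U2"),
        np.array(wdl, dtype=float),
        np.array(sess),
        np.array(subj),
    )
    return ts, skipped


# ---------------------------------------------------------------------------
# High-level trial-set preprocessing
# ---------------------------------------------------------------------------

def preprocess_trialset(trial_set: TrialSet, lo: float = 3.0, hi: float = 350.0,
                        order: int = 4, mains: float = 50.0, grubbs_alpha: float = 0.05,
                        reject_threshold: float = 0.10, do_notch: bool = True,
                        do_reject: bool = True, do_normalize: bool = True,
                        behavioral_flags: np.ndarray | None = None,
                        ) -> tuple[TrialSet, pd.DataFrame]:
    """Full conditioning chain on an epoched TrialSet: band-pass, notch,
    Grubbs trial rejection on the filtered signal, then per-session
    z-scoring.  Returns the clean set and the rejection report."""
    out = trial_set.with_signals(bandpass(trial_set.signals, trial_set.fs, lo, hi, order))
    if do_notch:
        out = out.with_signals(notch(out.signals, out.fs, mains=mains, upper=hi))
    if do_reject:
        out, report = reject_trials(out, threshold=reject_threshold,
                                    behavioral_flags=behavioral_flags, alpha=grubbs_alpha)
    else:
        report = pd.DataFrame(
            {"trial": np.arange(out.n_trials),
             "outlier_fraction": np.zeros(out.n_trials),
             "rejected": np.zeros(out.n_trials, dtype=bool),
             "reason": [""] * out.n_trials}
        )
    if do_normalize:
        out, _ = zscore_session(out)
    return out, report
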