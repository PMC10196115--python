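"""Morlet time-frequency power: scalograms, baseline z-normalization, and
the five-band interval statistics.

Power is the squared magnitude of the continuous complex-Morlet wavelet
transform, computed per trial and averaged across trials *after* the
transform, so induced (non-phase-locked) modulation remains visible.
Baseline normalization z-scores each frequency row against the [-1, 0] s
pre-stimulus interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import pywt
import scipy.stats as st

from .datatypes import BANDS, TrialSet
from .errors import DegenerateInputError, InvalidArgumentError

#: Star-level encoding for p-values (thresholds 0.05 / 0.01 / 0.001 / 0.0001).
STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    for thr, code in STAR_LEVELS:
        if p < thr:
            return code
    return "n.s."


def default_freqs(n: int = 60, lo: float = 3.0, hi: float = 120.0) -> np.ndarray:
    """Log-spaced scalogram frequency grid (default 60 points, 3-120 Hz)."""
    return np.geomspace(lo, hi, n)


@dataclass
class Scalogram:
    """Time-frequency power.  ``power`` is (n_freqs, n_times) for a single
    signal or (n_trials, n_freqs, n_times) for a trial stack; ``coi`` flags
    samples inside the cone of influence (edge-contaminated)."""

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray
    normalized: bool = False
    n_trials: int = 1
    coi: np.ndarray | None = None


def _morlet_bandwidth(n_cycles: float, center: float = 1.0) -> float:
    # complex Morlet 'cmorB-C': time-domain std at scale for frequency f is
    # sqrt(B/2)*C/f; matching n_cycles/(2*pi*f) gives B = 2*(n_cycles/(2*pi*C))^2
    return 2.0 * (n_cycles / (2.0 * np.pi * center)) ** 2


def cwt_complex(signal: np.ndarray, fs: float, freqs: np.ndarray,
                n_cycles: float = 6.0) -> np.ndarray:
    """Complex Morlet coefficients (n_freqs, n_samples) of a 1-D signal.

    The epoch is reflection-padded by four wavelet supports at the lowest
    frequency before the transform to suppress edge artifacts.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise InvalidArgumentError("empty frequency grid")
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise InvalidArgumentError("frequencies must lie in (0, fs/2)")
    x = np.asarray(signal, dtype=float)
    n = x.size
    pad = min(int(np.ceil(4.0 * n_cycles / (2.0 * np.pi * freqs.min()) * fs)), n - 1)
    xp = np.pad(x, pad, mode="reflect")
    C = 1.0
    B = _morlet_bandwidth(n_cycles, C)
    scales = C * fs / freqs
    coef, _ = pywt.cwt(xp, scales, f"cmor{B:.6f}-{C:.6f}",
                       sampling_period=1.0 / fs, method="fft")
    return coef[:, pad:pad + n]


def cwt_power(signal: np.ndarray, fs: float, freqs: np.ndarray | None = None,
              n_cycles: float = 6.0, onset_idx: int = 0) -> Scalogram:
    """Morlet scalogram (squared coefficient magnitude) of one signal."""
    if freqs is None:
        freqs = default_freqs()
    coef = cwt_complex(signal, fs, freqs, n_cycles)
    power = np.abs(coef) ** 2
    n = len(np.asarray(signal))
    times = (np.arange(n) - onset_idx) / fs
    sigma_t = n_cycles / (2.0 * np.pi * np.asarray(freqs, dtype=float))
    coi = (times[None, :] - times[0] < 2.0 * sigma_t[:, None]) | (
        times[-1] - times[None, :] < 2.0 * sigma_t[:, None]
    )
    return Scalogram(np.asarray(freqs, dtype=float), times, power, False, 1, coi)


def trialset_scalograms(trial_set: TrialSet, label: str | None = None,
                        hemisphere: str = "pooled",
                        freqs: np.ndarray | None = None,
                        n_cycles: float = 6.0) -> Scalogram:
    """Per-trial scalogram stack (n_trials, n_freqs, n_times) for a class."""
    from .evoked import _hemi_signals  # local import to avoid cycle

    ts = trial_set.select(label=label) if label is not None else trial_set
    if freqs is None:
        freqs = default_freqs()
    x = _hemi_signals(ts, hemisphere)
    onset = int(ts.onset_idx[0])
    stack = np.stack([
        np.abs(cwt_complex(x[i], ts.fs, freqs, n_cycles)) ** 2 for i in range(ts.n_trials)
    ])
    times = (np.arange(ts.n_samples) - onset) / ts.fs
    return Scalogram(np.asarray(freqs, dtype=float), times, stack, False, ts.n_trials)


def baseline_normalize(scalogram: Scalogram,
                       baseline_s: tuple[float, float] = (-1.0, 0.0)) -> Scalogram:
    """Z-score each frequency row against its pre-stimulus baseline interval
    (per trial when given a trial stack)."""
    sel = (scalogram.times >= baseline_s[0]) & (scalogram.times < baseline_s[1])
    if not sel.any():
        raise InvalidArgumentError("baseline interval lies outside the time axis")
    p = scalogram.power
    mu = p[..., sel].mean(axis=-1, keepdims=True)
    sd = p[..., sel].std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError("zero baseline variance at some frequency")
    return replace(scalogram, power=(p - mu) / sd, normalized=True)


def band_power(scalogram: Scalogram, band: tuple[str, float, float],
               interval_s: tuple[float, float]) -> np.ndarray:
    """Mean power over band x interval; returns per-trial values for a
    stack (or a scalar for a single scalogram)."""
    name, lo, hi = band
    fsel = (scalogram.freqs >= lo) & (scalogram.freqs <= hi)
    if not fsel.any():
        raise InvalidArgumentError(f"band {name} outside the frequency grid")
    tsel = (scalogram.times >= interval_s[0]) & (scalogram.times < interval_s[1])
    if not tsel.any():
        raise InvalidArgumentError("interval outside the epoch")
    sub = scalogram.power[..., fsel, :][..., tsel]
    return sub.mean(axis=(-2, -1))


def band_power_trace(scalogram: Scalogram, band: tuple[str, float, float]) -> np.ndarray:
    """Time-resolved band power (mean over the band's frequency rows)."""
    _, lo, hi = band
    fsel = (scalogram.freqs >= lo) & (scalogram.freqs <= hi)
    if not fsel.any():
        raise InvalidArgumentError("band outside the frequency grid")
    return scalogram.power[..., fsel, :].mean(axis=-2)


def band_power_table(trial_set: TrialSet, labels: tuple[str, ...] = ("HN", "NN", "NS"),
                     hemispheres: tuple[str, ...] = ("pooled",),
                     intervals: tuple[tuple[float, float], ...] = ((0.0, 0.5), (0.5, 5.0)),
                     baseline_s: tuple[float, float] = (-1.0, 0.0),
                     freqs: np.ndarray | None = None,
                     normalized: bool = True) -> pd.DataFrame:
    """Tidy per-trial band-power table over class x hemisphere x band x
    interval (plus the baseline interval itself)."""
    rows = []
    all_intervals = list(intervals) + [baseline_s]
    for lab in labels:
        sub = trial_set.select(label=lab)
        if sub.n_trials == 0:
            continue
        for hemi in hemispheres:
            scal = trialset_scalograms(sub, hemisphere=hemi, freqs=freqs)
            if normalized:
                scal = baseline_normalize(scal, baseline_s)
            for band in BANDS:
                for interval in all_intervals:
                    vals = band_power(scal, band, interval)
                    for i, v in enumerate(np.atleast_1d(vals)):
                        rows.append(
                            {
                                "label": lab,
                                "hemisphere": hemi,
                                "band": band[0],
                                "interval": f"[{interval[0]},{interval[1]})",
                                "is_baseline": interval == baseline_s,
                                "trial": i,
                                "power": float(v),
                            }
                        )
    return pd.DataFrame(rows)


def compare_band_power(values_a: np.ndarray, values_b: np.ndarray,
                       level: float = 0.05) -> dict:
    """Rank-sum comparison of two groups of band-power values with the
    star-level encoding; direction is the sign of mean(a) - mean(b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("need >= 2 values per group")
    res = st.ranksums(a, b)
    p = float(res.pvalue)
    return {
        "statistic": float(res.statistic),
        "pvalue": p,
        "significant": p < level,
        "direction": int(np.sign(a.mean() - b.mean())),
        "stars": star_code(p),
    }


def compare_band_power_classes(table: pd.DataFrame, label_a: str, label_b: str,
                               level: float = 0.05) -> pd.DataFrame:
    """Per band x interval rank-sum comparison between two classes from a
    band-power table produced by :func:`band_power_table`."""
    rows = []
    for (band, interval), grp in table[~table.is_baseline].groupby(["band", "interval"], sort=False):
        a = grp.loc[grp.label == label_a, "power"].to_numpy()
        b = grp.loc[grp.label == label_b, "power"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        res = compare_band_power(a, b, level)
        rows.append({"band": band, "interval": interval, "mean_a": a.mean(),
                     "mean_b": b.mean(), **res})
    return pd.DataFrame(rows)


def bilateral_band_power_comparison(trial_set: TrialSet, label: str,
                                    intervals: tuple[tuple[float, float], ...] = ((0.0, 0.5), (0.5, 5.0)),
                                    freqs: np.ndarray | None = None,
                                    level: float = 0.05) -> pd.DataFrame:
    """Paired signed-rank comparison of per-trial band power between the
    ipsi- and contralateral hemispheres."""
    sub = trial_set.select(label=label)
    scal = {h: baseline_normalize(trialset_scalograms(sub, hemisphere=h, freqs=freqs))
            for h in ("ipsi", "contra")}
    rows = []
    for band in BANDS:
        for interval in intervals:
            a = np.atleast_1d(band_power(scal["ipsi"], band, interval))
            b = np.atleast_1d(band_power(scal["contra"], band, interval))
            d = a - b
            if np.all(d == 0):
                p, statv = 1.0, 0.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = st.wilcoxon(a, b, zero_method="wilcox")
                p, statv = float(res.pvalue), float(res.statistic)
            rows.append(
                {
                    "band": band[0],
                    "interval": f"[{interval[0]},{interval[1]})",
                    "mean_ipsi": float(a.mean()),
                    "mean_contra": float(b.mean()),
                    "statistic": statv,
                    "pvalue": p,
                    "significant": p < level,
                    "direction": int(np.sign(a.mean() - b.mean())),
                    "stars": star_code(p),
                }
            )
    return pd.DataFrame(rows)
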