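"""Interhemispheric synchrony: time-frequency phase-locking value (PLV),
sliding-window Pearson correlation, and cross-correlation lag estimation.

PLV at (t, f) is |mean over a sliding window of exp(i*(phi_x - phi_y))|
with phases from the complex Morlet transform, computed per trial and then
averaged across trials; it is 1 for perfectly phase-locked signals and has
the small-sample null bias sqrt(pi/(4N)) for N independent phase samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st
from scipy.ndimage import uniform_filter1d

from .datatypes import TrialSet
from .errors import DegenerateInputError, InvalidArgumentError
from .spectral import cwt_complex, default_freqs


@dataclass
class PLVMap:
    """Time-frequency PLV, trial-averaged; ``plv`` raw in [0, 1] and
    ``plv_norm`` relative to the pre-stimulus baseline."""

    times: np.ndarray
    freqs: np.ndarray
    plv: np.ndarray
    plv_norm: np.ndarray | None
    window_ms: float
    n_trials: int


@dataclass
class CorrelationTrace:
    """Sliding-window Pearson correlation between hemispheres (mean +- SEM
    across trials) with per-sample significance vs the baseline."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    per_trial: np.ndarray
    window_ms: float
    step_ms: float
    significant: np.ndarray | None = None
    n_undefined: int = 0


@dataclass
class CrossCorrelation:
    """Normalized cross-correlation r_xy(k) over a symmetric lag range."""

    lags: np.ndarray           # samples
    lags_ms: np.ndarray
    r: np.ndarray
    lag_at_max_ms: float
    ambiguous: bool = False


@dataclass
class LagEstimate:
    lag_ms: float
    peak_r: float
    reliable: bool
    perm_threshold: float | None
    mean_xcorr: CrossCorrelation | None = None


def _pair_signals(trial_set: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    return trial_set.signals[:, 0, :], trial_set.signals[:, 1, :]


# ---------------------------------------------------------------------------
# Phase-locking value
# ---------------------------------------------------------------------------

def plv_timefreq(trials_left: np.ndarray, trials_right: np.ndarray, fs: float,
                 freqs: np.ndarray | None = None, window_ms: float = 500.0,
                 step_ms: float = 1.0, onset_idx: int = 0,
                 baseline_s: tuple[float, float] = (-1.0, 0.0),
                 n_cycles: float = 6.0, normalization: str = "subtract") -> PLVMap:
    """Sliding-window PLV map between paired trial stacks (n_trials, n_samples).

    Per trial the Morlet phase difference is averaged as a unit phasor over
    a centered sliding window of ``window_ms``; magnitudes are then averaged
    across trials.  The normalized variant removes the per-frequency
    baseline mean (``normalization='subtract'``, or ``'zscore'``).
    """
    L = np.asarray(trials_left, dtype=float)
    R = np.asarray(trials_right, dtype=float)
    if L.shape != R.shape:
        raise InvalidArgumentError("left/right trial stacks must be paired (same shape)")
    if L.ndim == 1:
        L, R = L[None, :], R[None, :]
    n_trials, n = L.shape
    w = int(round(window_ms / 1000.0 * fs))
    if w > n:
        raise InvalidArgumentError("window longer than the epoch")
    if freqs is None:
        freqs = default_freqs()
    step = max(int(round(step_ms / 1000.0 * fs)), 1)

    acc = np.zeros((len(freqs), n))
    for i in range(n_trials):
        cl = cwt_complex(L[i], fs, freqs, n_cycles)
        cr = cwt_complex(R[i], fs, freqs, n_cycles)
        u = cl * np.conj(cr)
        mag = np.abs(u)
        mag[mag == 0] = 1.0
        u /= mag
        re = uniform_filter1d(u.real, size=w, axis=-1, mode="nearest")
        im = uniform_filter1d(u.imag, size=w, axis=-1, mode="nearest")
        acc += np.hypot(re, im)
    plv = acc / n_trials
    half = w // 2
    centers = np.arange(half, n - (w - half) + 1, step)
    times = (centers - onset_idx) / fs
    plv = plv[:, centers]
    plv = np.clip(plv, 0.0, 1.0)
    base = (times >= baseline_s[0]) & (times < baseline_s[1])
    plv_norm = None
    if base.any():
        mu = plv[:, base].mean(axis=1, keepdims=True)
        if normalization == "zscore":
            sd = plv[:, base].std(axis=1, ddof=1, keepdims=True)
            sd[sd == 0] = 1.0
            plv_norm = (plv - mu) / sd
        else:
            plv_norm = plv - mu
    return PLVMap(times, np.asarray(freqs, dtype=float), plv, plv_norm,
                  window_ms, n_trials)


def plv_across_trials(trials_left: np.ndarray, trials_right: np.ndarray, fs: float,
                      freqs: np.ndarray | None = None, onset_idx: int = 0,
                      n_cycles: float = 6.0) -> PLVMap:
    """Alternative estimator: PLV across trials at each fixed (t, f)."""
    L = np.asarray(trials_left, dtype=float)
    R = np.asarray(trials_right, dtype=float)
    if L.shape != R.shape or L.ndim != 2:
        raise InvalidArgumentError("need paired 2-D trial stacks")
    if freqs is None:
        freqs = default_freqs()
    acc = np.zeros((len(freqs), L.shape[1]), dtype=complex)
    for i in range(L.shape[0]):
        u = cwt_complex(L[i], fs, freqs, n_cycles) * np.conj(cwt_complex(R[i], fs, freqs, n_cycles))
        mag = np.abs(u)
        mag[mag == 0] = 1.0
        acc += u / mag
    plv = np.clip(np.abs(acc) / L.shape[0], 0.0, 1.0)
    times = (np.arange(L.shape[1]) - onset_idx) / fs
    return PLVMap(times, np.asarray(freqs, dtype=float), plv, None, 0.0, L.shape[0])


def expected_null_plv(n: int) -> float:
    """Expected PLV of n independent uniform phases (Rayleigh-walk bias)."""
    return float(np.sqrt(np.pi / (4.0 * n)))


# ---------------------------------------------------------------------------
# Sliding correlation
# ---------------------------------------------------------------------------

def sliding_correlation(trials_left: np.ndarray, trials_right: np.ndarray, fs: float,
                        window_ms: float = 500.0, step_ms: float = 1.0,
                        onset_idx: int = 0,
                        baseline_s: tuple[float, float] | None = (-1.0, 0.0),
                        level: float = 0.05) -> CorrelationTrace:
    """Sliding-window Pearson correlation per trial, averaged across trials.

    Windows with zero variance in either signal yield an undefined
    coefficient; those are excluded from the mean and counted.  When a
    baseline interval is given, each window is tested against the trial's
    own baseline-mean correlation with a signed-rank test.
    """
    L = np.asarray(trials_left, dtype=float)
    R = np.asarray(trials_right, dtype=float)
    if L.shape != R.shape:
        raise InvalidArgumentError("left/right trial stacks must be paired")
    if L.ndim == 1:
        L, R = L[None, :], R[None, :]
    n_trials, n = L.shape
    w = int(round(window_ms / 1000.0 * fs))
    if w > n or w < 2:
        raise InvalidArgumentError("window must fit inside the epoch")
    step = max(int(round(step_ms / 1000.0 * fs)), 1)

    def wmean(x):
        return uniform_filter1d(x, size=w, axis=-1, mode="nearest")

    mx, my = wmean(L), wmean(R)
    mxy = wmean(L * R)
    mxx = wmean(L * L)
    myy = wmean(R * R)
    cov = mxy - mx * my
    vx = np.maximum(mxx - mx * mx, 0.0)
    vy = np.maximum(myy - my * my, 0.0)
    denom = np.sqrt(vx * vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    undefined = denom <= 1e-15
    r[undefined] = np.nan

    half = w // 2
    centers = np.arange(half, n - (w - half) + 1, step)
    times = (centers - onset_idx) / fs
    r = np.clip(r[:, centers], -1.0, 1.0)
    n_undef = int(np.isnan(r).sum())
    mean = np.nanmean(r, axis=0)
    with np.errstate(invalid="ignore"):
        sem = np.nanstd(r, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(r), axis=0))

    significant = None
    if baseline_s is not None and n_trials >= 2:
        base = (times >= baseline_s[0]) & (times < baseline_s[1])
        if base.any():
            base_mean = np.nanmean(r[:, base], axis=1, keepdims=True)
            diff = r - base_mean
            p = np.ones(r.shape[1])
            valid = ~np.any(np.isnan(diff), axis=0)
            nz = valid & np.any(diff != 0, axis=0)
            if nz.any():
                res = st.wilcoxon(diff[:, nz], axis=0, zero_method="wilcox")
                p[nz] = np.nan_to_num(res.pvalue, nan=1.0)
            significant = p < level
    return CorrelationTrace(times, mean, sem, r, window_ms, step_ms,
                            significant, n_undef)


# ---------------------------------------------------------------------------
# Cross-correlation
# ---------------------------------------------------------------------------

def cross_correlation(x: np.ndarray, y: np.ndarray, max_lag: int,
                      fs: float = 1000.0) -> CrossCorrelation:
    """Biased-estimator normalized cross-correlation over lags |k| <= max_lag.

    C_xy(k) = (1/T) * sum (x_i - xbar)(y_{i+k} - ybar), normalized by the
    population standard deviations S_x S_y, so r_xx(0) = 1 exactly.
    Positive lag means y lags x (y is a delayed copy of x at lag +k).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidArgumentError("signals must have equal length")
    T = x.size
    if max_lag >= T:
        raise InvalidArgumentError("max_lag must be smaller than the signal length")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt(np.mean(xc * xc))
    sy = np.sqrt(np.mean(yc * yc))
    if sx == 0 or sy == 0:
        raise DegenerateInputError("constant signal in cross-correlation")
    full = np.correlate(yc, xc, mode="full") / T  # index T-1+k holds C_xy(k)
    lags = np.arange(-max_lag, max_lag + 1)
    r = full[T - 1 + lags] / (sx * sy)
    imax = int(np.argmax(r))
    near = np.flatnonzero(r >= r[imax] - 1e-6)
    ambiguous = len(near) > 1
    best = int(near[0]) if ambiguous else imax
    lags_ms = lags * 1000.0 / fs
    return CrossCorrelation(lags, lags_ms, r, float(lags_ms[best]), ambiguous)


def estimate_interhemispheric_lag(trial_set: TrialSet, max_lag_ms: float = 100.0,
                                  interval_s: tuple[float, float] | None = None,
                                  n_permutations: int = 0,
                                  rng: np.random.Generator | None = None) -> LagEstimate:
    """Time lag between hemispheres: per-trial cross-correlation averaged
    over trials; the lag is the argmax of the average (ms, positive =
    contralateral lags ipsilateral).

    With ``n_permutations`` > 0 the peak is compared against mismatched
    trial pairings: if it does not exceed the 95th percentile of permuted
    peaks the estimate is flagged unreliable.
    """
    L, R = _pair_signals(trial_set)
    fs = trial_set.fs
    if interval_s is not None:
        t = trial_set.times()
        sel = (t >= interval_s[0]) & (t < interval_s[1])
        L, R = L[:, sel], R[:, sel]
    max_lag = int(round(max_lag_ms / 1000.0 * fs))

    def avg_xcorr(left, right):
        acc = None
        for i in range(left.shape[0]):
            cc = cross_correlation(left[i], right[i], max_lag, fs)
            acc = cc.r if acc is None else acc + cc.r
        return acc / left.shape[0], cc.lags

    r_mean, lags = avg_xcorr(L, R)
    imax = int(np.argmax(r_mean))
    near = np.flatnonzero(r_mean >= r_mean[imax] - 1e-6)
    lag_ms = float(lags[near[0]] * 1000.0 / fs)
    peak = float(r_mean[imax])

    reliable, thresh = True, None
    if n_permutations > 0:
        if rng is None:
            rng = np.random.default_rng()
        peaks = []
        for _ in range(n_permutations):
            perm = rng.permutation(L.shape[0])
            rp, _ = avg_xcorr(L, R[perm])
            peaks.append(rp.max())
        thresh = float(np.quantile(peaks, 0.95))
        reliable = peak > thresh
    cc = CrossCorrelation(lags, lags * 1000.0 / fs, r_mean, lag_ms, len(near) > 1)
    return LagEstimate(lag_ms, peak, reliable, thresh, cc)


# ---------------------------------------------------------------------------
# Dip-recovery readout
# ---------------------------------------------------------------------------

def below_baseline_recovery(times: np.ndarray, trace: np.ndarray,
                            baseline_s: tuple[float, float] = (-1.0, 0.0),
                            start_after_s: float = 0.2, k: float = 2.0,
                            min_run_s: float = 0.2) -> float | None:
    """End time of the last sustained below-baseline excursion of a trace.

    The threshold is baseline mean - k * baseline sd of the trace; runs
    shorter than ``min_run_s`` are ignored.  Returns None when no sustained
    excursion exists (e.g. uncoupled or unstimulated data).
    """
    base = (times >= baseline_s[0]) & (times < baseline_s[1])
    if not base.any():
        raise InvalidArgumentError("baseline outside trace")
    mu = float(np.nanmean(trace[base]))
    sd = float(np.nanstd(trace[base]))
    below = (trace < mu - k * sd) & (times >= start_after_s)
    if not below.any():
        return None
    dt = float(np.median(np.diff(times)))
    min_run = max(int(round(min_run_s / dt)), 1)
    # find contiguous runs
    idx = np.flatnonzero(below)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    runs = [r for r in runs if len(r) >= min_run]
    if not runs:
        return None
    return float(times[runs[-1][-1]])
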