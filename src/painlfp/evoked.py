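"""Evoked-potential averaging, P1/N1/P2 parametrization, and the samplewise
and bilateral nonparametric statistics.

An evoked potential (EP) is the stimulus-locked trial average; P1 is its
first positive peak, N1 the first negative trough, P2 an optional second
positive peak.  Latencies are reported in ms from stimulus onset and
amplitudes in the normalized z-units of the preprocessed signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter as sg_savgol
from scipy.stats import false_discovery_control

from .datatypes import TrialSet
from .errors import InsufficientDataError, InvalidArgumentError

_HEMI_INDEX = {"ipsi": 0, "contra": 1}


@dataclass
class EPWaveform:
    """Trial-averaged evoked potential with across-trial SEM."""

    times: np.ndarray           # seconds relative to onset
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    label: str
    hemisphere: str             # 'ipsi' | 'contra' | 'pooled'


@dataclass
class EPParams:
    """P1/N1 (and optional P2) latencies (ms) and amplitudes (z-units).

    Absent components are None.  ``p2_present`` is True only when a positive
    local maximum follows N1 by more than 3x the baseline SEM.
    """

    p1_latency_ms: float | None = None
    p1_amp: float | None = None
    n1_latency_ms: float | None = None
    n1_amp: float | None = None
    p2_present: bool = False
    p2_latency_ms: float | None = None
    p2_amp: float | None = None


@dataclass
class SamplewiseTestResult:
    """Per-sample nonparametric test along the epoch."""

    times: np.ndarray
    statistic: np.ndarray
    pvalue: np.ndarray
    significant: np.ndarray
    test: str
    pair: str
    level: float


def _hemi_signals(trial_set: TrialSet, hemisphere: str) -> np.ndarray:
    if hemisphere == "pooled":
        return trial_set.signals.mean(axis=1)
    try:
        return trial_set.signals[:, _HEMI_INDEX[hemisphere], :]
    except KeyError:
        raise InvalidArgumentError(f"unknown hemisphere {hemisphere!r}") from None


def compute_ep(trial_set: TrialSet, label: str | None = None,
               hemisphere: str = "pooled") -> EPWaveform:
    """Average time-aligned trials into an evoked potential (mean +- SEM)."""
    ts = trial_set.select(label=label) if label is not None else trial_set
    if ts.n_trials < 2:
        raise InsufficientDataError("EP averaging needs at least 2 trials")
    x = _hemi_signals(ts, hemisphere)
    mean = x.mean(axis=0)
    sem = x.std(axis=0, ddof=1) / np.sqrt(ts.n_trials)
    return EPWaveform(ts.times(), mean, sem, ts.n_trials,
                      label if label is not None else "all", hemisphere)


# ---------------------------------------------------------------------------
# Parametrization
# ---------------------------------------------------------------------------

def extract_ep_params(ep: EPWaveform,
                      p1_window_ms: tuple[float, float] = (20.0, 130.0),
                      n1_window_ms: tuple[float, float] = (80.0, 260.0),
                      p2_max_ms: float = 400.0,
                      baseline_s: tuple[float, float] = (-1.0, 0.0),
                      smooth_ms: float = 25.0, smooth_order: int = 3) -> EPParams:
    """Extract P1/N1/P2 from an averaged EP.

    The trace is first smoothed with a peak-preserving Savitzky-Golay
    filter (``smooth_ms`` window; 0 disables it) so residual averaging
    noise does not hijack the extremum search.  P1 is the largest positive
    value in the P1 window (earliest sample on ties), N1 the most negative
    value in the N1 window occurring after P1; both must have the proper
    sign or the component is reported absent.  P2 is the earliest positive
    local maximum after N1 exceeding 3x the mean baseline SEM.
    """
    t_ms = ep.times * 1000.0
    params = EPParams()
    if smooth_ms and len(ep.times) > 1:
        dt_ms = float(np.median(np.diff(t_ms)))
        w = max(int(round(smooth_ms / dt_ms)) | 1, smooth_order + 2 - (smooth_order % 2))
        y = sg_savgol(ep.mean, w, smooth_order) if w < len(ep.mean) else ep.mean
    else:
        y = ep.mean

    sel1 = (t_ms >= p1_window_ms[0]) & (t_ms <= p1_window_ms[1])
    if not sel1.any():
        raise InvalidArgumentError("P1 window lies outside the epoch")
    seg = y[sel1]
    i1 = int(np.argmax(seg))
    if seg[i1] > 0:
        params.p1_latency_ms = float(t_ms[sel1][i1])
        params.p1_amp = float(seg[i1])

    sel2 = (t_ms >= n1_window_ms[0]) & (t_ms <= n1_window_ms[1])
    if params.p1_latency_ms is not None:
        sel2 &= t_ms > params.p1_latency_ms
    if sel2.any():
        seg = y[sel2]
        i2 = int(np.argmin(seg))
        if seg[i2] < 0:
            params.n1_latency_ms = float(t_ms[sel2][i2])
            params.n1_amp = float(seg[i2])

    if params.n1_latency_ms is not None:
        base = (ep.times >= baseline_s[0]) & (ep.times < baseline_s[1])
        thresh = 3.0 * float(ep.sem[base].mean()) if base.any() else 0.0
        sel3 = (t_ms > params.n1_latency_ms) & (t_ms <= p2_max_ms)
        idx = np.flatnonzero(sel3)
        for j in (idx[1:-1] if len(idx) > 2 else []):
            if y[j] > thresh and y[j] >= y[j - 1] and y[j] > y[j + 1]:
                params.p2_present = True
                params.p2_latency_ms = float(t_ms[j])
                params.p2_amp = float(y[j])
                break
    return params


def extract_ep_params_per_trial(trial_set: TrialSet, label: str | None = None,
                                hemisphere: str = "pooled",
                                smooth_ms: float = 20.0,
                                latency_halfwin_ms: float = 40.0,
                                reference: EPParams | None = None) -> pd.DataFrame:
    """Guided single-trial P1/N1 parametrization for dispersion statistics.

    Single trials are too noisy for unguided peak picking, so each trial is
    lightly smoothed (moving average of ``smooth_ms``) and parametrized
    relative to the class-average EP: the amplitude is the smoothed trial
    value at the reference latency (unbiased under additive noise) and the
    latency is the local extremum within +-``latency_halfwin_ms`` of it.
    """
    ts = trial_set.select(label=label) if label is not None else trial_set
    if reference is None:
        reference = extract_ep_params(compute_ep(ts, hemisphere=hemisphere))
    if reference.p1_latency_ms is None or reference.n1_latency_ms is None:
        raise InsufficientDataError("reference EP lacks P1/N1; cannot guide trials")
    x = _hemi_signals(ts, hemisphere)
    width = max(int(round(smooth_ms / 1000.0 * ts.fs)), 1)
    xs = uniform_filter1d(x, size=width, axis=-1, mode="nearest")
    t_ms = ts.times() * 1000.0

    def window(center: float) -> np.ndarray:
        return (t_ms >= center - latency_halfwin_ms) & (t_ms <= center + latency_halfwin_ms)

    rows = []
    w1, w2 = window(reference.p1_latency_ms), window(reference.n1_latency_ms)
    ip1 = int(np.argmin(np.abs(t_ms - reference.p1_latency_ms)))
    in1 = int(np.argmin(np.abs(t_ms - reference.n1_latency_ms)))
    for i in range(ts.n_trials):
        tr = xs[i]
        rows.append(
            {
                "trial": i,
                "p1_latency_ms": float(t_ms[w1][np.argmax(tr[w1])]),
                "p1_amp": float(tr[ip1]),
                "n1_latency_ms": float(t_ms[w2][np.argmin(tr[w2])]),
                "n1_amp": float(tr[in1]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Samplewise statistics
# ---------------------------------------------------------------------------

def _safe_wilcoxon(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired signed-rank per column; all-zero columns get p = 1 by convention."""
    nz = np.any(diff != 0, axis=0)
    stat = np.zeros(diff.shape[1])
    p = np.ones(diff.shape[1])
    if nz.any():
        res = st.wilcoxon(diff[:, nz], axis=0, zero_method="wilcox")
        stat[nz] = res.statistic
        p[nz] = res.pvalue
    return stat, np.nan_to_num(p, nan=1.0)


def samplewise_vs_baseline(trial_set: TrialSet, label: str | None = None,
                           baseline_s: tuple[float, float] = (-1.0, 0.0),
                           level: float = 0.05, hemisphere: str = "pooled",
                           fdr: bool = False) -> SamplewiseTestResult:
    """Wilcoxon signed-rank test of every post-onset sample against each
    trial's own baseline mean (no multiplicity correction by default;
    ``fdr=True`` switches on Benjamini-Hochberg)."""
    ts = trial_set.select(label=label) if label is not None else trial_set
    x = _hemi_signals(ts, hemisphere)
    t = ts.times()
    base = (t >= baseline_s[0]) & (t < baseline_s[1])
    if not base.any():
        raise InvalidArgumentError("baseline interval lies outside the epoch")
    post = t >= 0
    diff = x[:, post] - x[:, base].mean(axis=1, keepdims=True)
    stat, p = _safe_wilcoxon(diff)
    p_eff = false_discovery_control(p) if fdr else p
    return SamplewiseTestResult(t[post], stat, p, p_eff < level,
                                "wilcoxon-signed-rank", f"{ts.labels[0] if ts.n_trials else ''} vs baseline",
                                level)


def compare_classes_samplewise(trials_a: TrialSet, trials_b: TrialSet,
                               level: float = 0.05, hemisphere: str = "pooled",
                               fdr: bool = False) -> SamplewiseTestResult:
    """Unpaired rank-sum test between two classes at every sample."""
    xa = _hemi_signals(trials_a, hemisphere)
    xb = _hemi_signals(trials_b, hemisphere)
    if xa.shape[1] != xb.shape[1]:
        raise InvalidArgumentError("trial sets have different epoch lengths")
    res = st.ranksums(xa, xb, axis=0)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    p_eff = false_discovery_control(p) if fdr else p
    return SamplewiseTestResult(trials_a.times(), res.statistic, p, p_eff < level,
                                "wilcoxon-rank-sum", "a vs b", level)


# ---------------------------------------------------------------------------
# Parameter-level statistics
# ---------------------------------------------------------------------------

def compare_ep_params(params_a: pd.DataFrame, params_b: pd.DataFrame,
                      names: tuple[str, str] = ("HN", "NN")) -> pd.DataFrame:
    """Per-parameter mean +- SEM for each class plus the rank-sum p-value.

    A parameter missing (NaN) in more than half the trials of either class
    is reported as undetermined (NaN summaries, p = NaN).
    """
    rows = []
    for col in ("p1_latency_ms", "n1_latency_ms", "p1_amp", "n1_amp"):
        a = params_a[col].to_numpy(dtype=float)
        b = params_b[col].to_numpy(dtype=float)
        if np.isnan(a).mean() > 0.5 or np.isnan(b).mean() > 0.5:
            rows.append({"parameter": col, f"mean_{names[0]}": np.nan,
                         f"sem_{names[0]}": np.nan, f"mean_{names[1]}": np.nan,
                         f"sem_{names[1]}": np.nan, "pvalue": np.nan,
                         "determined": False})
            continue
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        p = float(st.ranksums(a, b).pvalue)
        rows.append(
            {
                "parameter": col,
                f"mean_{names[0]}": float(a.mean()),
                f"sem_{names[0]}": float(a.std(ddof=1) / np.sqrt(len(a))),
                f"mean_{names[1]}": float(b.mean()),
                f"sem_{names[1]}": float(b.std(ddof=1) / np.sqrt(len(b))),
                "pvalue": p,
                "determined": True,
            }
        )
    return pd.DataFrame(rows)


def bilateral_ep_comparison(trial_set: TrialSet, label: str | None = None) -> pd.DataFrame:
    """Paired signed-rank comparison of per-trial P1/N1 amplitude and latency
    between the two hemispheres (same trials, hemisphere pair)."""
    ts = trial_set.select(label=label) if label is not None else trial_set
    ref = {
        h: extract_ep_params(compute_ep(ts, hemisphere=h)) for h in ("ipsi", "contra")
    }
    for h, r in ref.items():
        if r.p1_latency_ms is None or r.n1_latency_ms is None:
            raise InsufficientDataError(f"{h} average EP lacks P1/N1")
    per = {h: extract_ep_params_per_trial(ts, hemisphere=h, reference=ref[h])
           for h in ("ipsi", "contra")}
    rows = []
    for col, absolute in (("p1_amp", True), ("n1_amp", True),
                          ("p1_latency_ms", False), ("n1_latency_ms", False)):
        a = per["ipsi"][col].to_numpy(dtype=float)
        b = per["contra"][col].to_numpy(dtype=float)
        if absolute:
            a, b = np.abs(a), np.abs(b)
        d = a - b
        if np.all(d == 0):
            p = 1.0
            statv = 0.0
        else:
            res = st.wilcoxon(a, b, zero_method="wilcox")
            p = float(res.pvalue)
            statv = float(res.statistic)
        rows.append(
            {
                "parameter": (f"|{col}|" if absolute else col),
                "mean_ipsi": float(a.mean()),
                "mean_contra": float(b.mean()),
                "statistic": statv,
                "pvalue": p,
            }
        )
    return pd.DataFrame(rows)
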