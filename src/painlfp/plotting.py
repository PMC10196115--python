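"""Figure helpers: EP traces with significance dots, scalograms,
feature-selection maps, and correlation traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_ep(ep, test=None, ax=None, color="C0"):
    """Mean +- SEM evoked potential; optional samplewise-significance dots."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    ax.fill_between(ep.times, ep.mean - ep.sem, ep.mean + ep.sem,
                    alpha=0.3, color=color, lw=0)
    ax.plot(ep.times, ep.mean, color=color, label=f"{ep.label} ({ep.n_trials} trials)")
    if test is not None and test.significant.any():
        sig_t = test.times[test.significant]
        ax.plot(sig_t, np.full_like(sig_t, ax.get_ylim()[0] * 0.95), ".",
                color="green", ms=2)
    ax.axvline(0.0, ls="--", color="k", lw=0.8)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("normalized LFP (z)")
    ax.legend(frameon=False)
    return ax


def plot_scalogram(scal, ax=None, cmap="magma", vlim=None):
    """Time-frequency power map (log frequency axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    power = scal.power if scal.power.ndim == 2 else scal.power.mean(axis=0)
    kw = {}
    if vlim is not None:
        kw = {"vmin": -vlim, "vmax": vlim, "cmap": "RdBu_r"}
    else:
        kw = {"cmap": cmap}
    pcm = ax.pcolormesh(scal.times, scal.freqs, power, shading="auto", **kw)
    ax.set_yscale("log")
    ax.axvline(0.0, ls="--", color="w", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    plt.colorbar(pcm, ax=ax, label="power" + (" (baseline z)" if scal.normalized else ""))
    return ax


def plot_feature_map(counts, window_ms=30.0, ax=None):
    """Fig-style map of mRMR-selected feature counts over band x time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.8))
    pcm = ax.pcolormesh(np.asarray(counts.columns, dtype=float) * window_ms / 1000.0,
                        np.arange(len(counts.index)), counts.to_numpy(),
                        shading="auto", cmap="viridis")
    ax.set_yticks(np.arange(len(counts.index)), counts.index)
    ax.set_xlabel("window start (s)")
    plt.colorbar(pcm, ax=ax, label="selected features")
    return ax


def plot_correlation_trace(trace, ax=None):
    """Sliding-window interhemispheric correlation (mean +- SEM)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.fill_between(trace.times, trace.mean - trace.sem, trace.mean + trace.sem,
                    alpha=0.3, lw=0)
    ax.plot(trace.times, trace.mean)
    if trace.significant is not None and trace.significant.any():
        st = trace.times[trace.significant]
        ax.plot(st, np.full_like(st, np.nanmin(trace.mean)), ".", color="green", ms=2)
    ax.axvline(0.0, ls="--", color="k", lw=0.8)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("interhemispheric PCC")
    return ax
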