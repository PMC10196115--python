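"""End-to-end experiment recipes on synthetic data.

These functions tie the generator to the analysis stages and are shared by
the acceptance script, the test suite, and the CLI `run` verb: evoked-
potential parameter recovery at study-scale trial counts, withdrawal-
latency statistics, desk-scale decoding runs, and coupling-dip recovery.
"""

from __future__ import annotations

import numpy as np

from .connectivity import below_baseline_recovery, sliding_correlation
from .datatypes import SimConfig
from .decoding import extract_mav_features, train_eval_svm
from .evoked import compute_ep, extract_ep_params
from .preprocess import preprocess_trialset
from .simulate import generate_trial_set


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2**31) from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


# ---------------------------------------------------------------------------
# Evoked-potential recovery
# ---------------------------------------------------------------------------

def ep_recovery_run(seed: int, n_hn: int = 657, n_nn: int = 533) -> dict:
    """One EP-recovery experiment: generate HN/NN trials at study-scale
    counts, preprocess, average, parametrize the pooled EP per class.

    Returns {'HN': EPParams, 'NN': EPParams}.
    """
    cfg = SimConfig(n_trials={"HN": n_hn, "NN": n_nn}, seed=seed)
    ts = generate_trial_set(cfg)
    clean, _ = preprocess_trialset(ts)
    return {lab: extract_ep_params(compute_ep(clean, label=lab)) for lab in ("HN", "NN")}


def ep_recovery_summary(seeds: list[int], n_hn: int = 657, n_nn: int = 533) -> dict:
    """Seed-averaged recovered EP parameters and HN/NN amplitude ratios."""
    acc: dict[str, list[float]] = {
        "hn_p1_latency_ms": [], "hn_n1_latency_ms": [],
        "hn_p1_amp": [], "hn_n1_amp": [],
        "nn_p1_latency_ms": [], "nn_p1_amp": [], "nn_n1_amp": [],
    }
    for seed in seeds:
        res = ep_recovery_run(seed, n_hn, n_nn)
        acc["hn_p1_latency_ms"].append(res["HN"].p1_latency_ms)
        acc["hn_n1_latency_ms"].append(res["HN"].n1_latency_ms)
        acc["hn_p1_amp"].append(res["HN"].p1_amp)
        acc["hn_n1_amp"].append(res["HN"].n1_amp)
        acc["nn_p1_latency_ms"].append(res["NN"].p1_latency_ms)
        acc["nn_p1_amp"].append(res["NN"].p1_amp)
        acc["nn_n1_amp"].append(res["NN"].n1_amp)
    out = {k: float(np.mean(v)) for k, v in acc.items()}
    out["p1_amp_ratio"] = out["hn_p1_amp"] / out["nn_p1_amp"]
    out["n1_amp_ratio"] = abs(out["hn_n1_amp"]) / abs(out["nn_n1_amp"])
    out["n_seeds"] = len(seeds)
    return out


def withdrawal_latency_mean(seed: int, n_trials: int = 500) -> float:
    """Sample mean (ms) of generated HN paw-withdrawal latencies."""
    cfg = SimConfig(n_trials={"HN": n_trials}, seed=seed, artifact_rate=0.0)
    ts = generate_trial_set(cfg)
    return float(np.nanmean(ts.withdrawal_ms))


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decoding_experiment(seed: int, n_per_class: int = 70,
                        pairs: tuple[tuple[str, str], ...] = (("HN", "NS"), ("NN", "NS")),
                        k_grid: tuple[int, ...] = (40,),
                        n_splits: int = 10, shuffle_labels: bool = False) -> dict:
    """Desk-scale decoding run: generate all three classes once, extract
    MAV features, and cross-validate an SVM for each requested class pair.

    Returns {pair_name: ClassifierResult}.  ``shuffle_labels`` permutes the
    labels (chance-level control for the no-leakage property).
    """
    cfg = SimConfig(
        n_trials={"HN": n_per_class, "NN": n_per_class, "NS": n_per_class},
        seed=seed, artifact_rate=0.0,
    )
    ts = generate_trial_set(cfg)
    clean, _ = preprocess_trialset(ts, do_reject=False)
    fm = extract_mav_features(clean)
    rng = np.random.default_rng(seed + 7)
    results = {}
    for a, b in pairs:
        sel = np.isin(fm.labels, (a, b))
        X, y, subj = fm.values[sel], fm.labels[sel].copy(), fm.subjects[sel]
        if shuffle_labels:
            y = rng.permutation(y)
        results[f"{a}-{b}"] = train_eval_svm(
            X, y, subjects=subj, scheme="kfold", n_splits=n_splits,
            k_grid=k_grid, seed=seed,
        )
    return results


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def coupling_recovery_run(seed: int, n_trials: int = 120,
                          window_ms: float = 500.0) -> dict:
    """Read the post-stimulus coupling dip back from the sliding-window
    correlation trace of generated HN trials.

    Returns the recovery time (end of the sustained below-baseline
    interval, seconds after onset; None if not detected) along with the
    trace and the generator's true recovery time.
    """
    cfg = SimConfig(n_trials={"HN": n_trials}, seed=seed, artifact_rate=0.0)
    ts = generate_trial_set(cfg)
    clean, _ = preprocess_trialset(ts, do_reject=False)
    trace = sliding_correlation(
        clean.signals[:, 0, :], clean.signals[:, 1, :], clean.fs,
        window_ms=window_ms, step_ms=5.0, onset_idx=int(clean.onset_idx[0]),
    )
    cspec = ts.meta["coupling_spec"]
    true_recovery = cspec.dip_onset_s + cspec.dip_duration_s
    rec = below_baseline_recovery(trace.times, trace.mean)
    return {"recovery_s": rec, "true_recovery_s": true_recovery, "trace": trace}
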