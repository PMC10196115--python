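"""Pipeline orchestration: validated YAML configuration, stage toggles,
and end-to-end runs producing the full result set (EP tables, band-power
statistics, decoding tables, connectivity traces) plus a run report."""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .connectivity import estimate_interhemispheric_lag, plv_timefreq, sliding_correlation
from .datatypes import SimConfig, TrialSet
from .decoding import extract_mav_features, train_eval_svm
from .errors import PainLFPError
from .evoked import compare_ep_params, compute_ep, extract_ep_params, extract_ep_params_per_trial
from .io import load_trialset, save_trialset, write_events_csv
from .preprocess import preprocess_trialset
from .simulate import generate_trial_set
from .spectral import band_power_table, compare_band_power_classes, default_freqs


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True


class SimulateSection(_Section):
    n_hn: int = 60
    n_nn: int = 60
    n_ns: int = 60
    artifact_rate: float = 0.02
    noise_sd: float = 1.0


class PreprocessSection(_Section):
    lo_hz: float = 3.0
    hi_hz: float = 350.0
    order: int = 4
    mains_hz: float = 50.0
    grubbs_alpha: float = 0.05
    reject_threshold: float = 0.10


class EPSection(_Section):
    p1_window_ms: tuple[float, float] = (20.0, 130.0)
    n1_window_ms: tuple[float, float] = (80.0, 260.0)


class SpectralSection(_Section):
    n_freqs: int = 40
    f_lo: float = 3.0
    f_hi: float = 120.0


class DecodeSection(_Section):
    pairs: list[str] = Field(default_factory=lambda: ["HN-NS", "NN-NS", "HN-NN"])
    scheme: str = "kfold"
    n_splits: int = 10
    k_grid: list[int] = Field(default_factory=lambda: [40])


class ConnectivitySection(_Section):
    window_ms: float = 500.0
    step_ms: float = 5.0
    max_lag_ms: float = 100.0
    plv_n_freqs: int = 12


class PipelineConfig(BaseModel):
    """Whole-run configuration; round-trips losslessly through YAML and
    rejects unknown keys."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    input_container: str | None = None   # when set, simulate is skipped
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    ep: EPSection = Field(default_factory=EPSection)
    spectral: SpectralSection = Field(default_factory=SpectralSection)
    decode: DecodeSection = Field(default_factory=DecodeSection)
    connectivity: ConnectivitySection = Field(default_factory=ConnectivitySection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages and write all result files under
    ``outdir``; returns the run report (also written as report.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {},
                    "warnings": []}
    t_start = time.time()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            ts = _stage_input(config, outdir, report)
            clean = _stage_preprocess(config, ts, outdir, report)
            if config.ep.enabled:
                _stage_ep(config, clean, outdir, report)
            else:
                report["stages"]["ep"] = {"skipped": True}
            if config.spectral.enabled:
                _stage_spectral(config, clean, outdir, report)
            else:
                report["stages"]["spectral"] = {"skipped": True}
            if config.decode.enabled:
                _stage_decode(config, clean, outdir, report)
            else:
                report["stages"]["decode"] = {"skipped": True}
            if config.connectivity.enabled:
                _stage_connectivity(config, clean, outdir, report)
            else:
                report["stages"]["connectivity"] = {"skipped": True}
        except PainLFPError as exc:
            report["failed_stage"] = getattr(exc, "stage", "unknown")
            report["error"] = str(exc)
            _write_report(report, outdir, t_start)
            raise
    report["warnings"] = [str(w.message) for w in caught]
    _write_report(report, outdir, t_start)
    return report


def _write_report(report: dict, outdir: Path, t_start: float) -> None:
    report["elapsed_s"] = round(time.time() - t_start, 2)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))


def _stage_input(config: PipelineConfig, outdir: Path, report: dict) -> TrialSet:
    if config.input_container:
        ts = load_trialset(config.input_container)
        report["stages"]["input"] = {"source": config.input_container,
                                     "n_trials": ts.n_trials}
        return ts
    s = config.simulate
    cfg = SimConfig(
        n_trials={k: v for k, v in
                  (("HN", s.n_hn), ("NN", s.n_nn), ("NS", s.n_ns)) if v > 0},
        seed=config.seed, artifact_rate=s.artifact_rate, noise_sd=s.noise_sd,
    )
    ts = generate_trial_set(cfg)
    save_trialset(ts, outdir / "trials.h5")
    write_events_csv(ts, outdir / "events.csv")
    report["stages"]["input"] = {"source": "simulate", "n_trials": ts.n_trials,
                                 "n_artifact": int(len(ts.meta.get("artifact_trials", [])))}
    return ts


def _stage_preprocess(config: PipelineConfig, ts: TrialSet, outdir: Path,
                      report: dict) -> TrialSet:
    p = config.preprocess
    if not p.enabled:
        report["stages"]["preprocess"] = {"skipped": True, "n_out": ts.n_trials}
        return ts
    clean, rej = preprocess_trialset(
        ts, lo=p.lo_hz, hi=p.hi_hz, order=p.order, mains=p.mains_hz,
        grubbs_alpha=p.grubbs_alpha, reject_threshold=p.reject_threshold,
    )
    rej.to_csv(outdir / "rejection_report.csv", index=False)
    report["stages"]["preprocess"] = {
        "n_in": ts.n_trials,
        "n_rejected": int(rej.rejected.sum()),
        "n_out": clean.n_trials,
    }
    return clean


def _stage_ep(config: PipelineConfig, clean: TrialSet, outdir: Path, report: dict) -> None:
    traces, rows = [], {}
    for lab in ("HN", "NN"):
        if (clean.labels == lab).sum() < 2:
            continue
        ep = compute_ep(clean, label=lab)
        traces.append(pd.DataFrame({"time_s": ep.times, f"mean_{lab}": ep.mean,
                                    f"sem_{lab}": ep.sem}).set_index("time_s"))
        prm = extract_ep_params(ep, config.ep.p1_window_ms, config.ep.n1_window_ms)
        rows[lab] = prm
    if traces:
        pd.concat(traces, axis=1).to_csv(outdir / "ep_traces.csv")
    params_df = pd.DataFrame(
        [{"label": lab, **vars(prm)} for lab, prm in rows.items()]
    )
    params_df.to_csv(outdir / "ep_params.csv", index=False)
    if {"HN", "NN"} <= set(rows):
        per = {lab: extract_ep_params_per_trial(clean, label=lab, reference=rows[lab])
               for lab in ("HN", "NN")}
        compare_ep_params(per["HN"], per["NN"]).to_csv(outdir / "ep_stats.csv", index=False)
    report["stages"]["ep"] = {"classes": list(rows), "n_in": clean.n_trials}


def _stage_spectral(config: PipelineConfig, clean: TrialSet, outdir: Path,
                    report: dict) -> None:
    freqs = default_freqs(config.spectral.n_freqs, config.spectral.f_lo,
                          config.spectral.f_hi)
    table = band_power_table(clean, freqs=freqs)
    table.to_csv(outdir / "band_power.csv", index=False)
    stats = []
    for a, b in (("HN", "NS"), ("NN", "NS"), ("HN", "NN")):
        if {a, b} <= set(np.unique(clean.labels)):
            df = compare_band_power_classes(table, a, b)
            df.insert(0, "pair", f"{a}-{b}")
            stats.append(df)
    if stats:
        pd.concat(stats).to_csv(outdir / "band_power_stats.csv", index=False)
    report["stages"]["spectral"] = {"n_in": clean.n_trials, "n_freqs": len(freqs)}


def _stage_decode(config: PipelineConfig, clean: TrialSet, outdir: Path,
                  report: dict) -> None:
    fm = extract_mav_features(clean)
    rows = []
    for pair in config.decode.pairs:
        a, b = pair.split("-")
        sel = np.isin(fm.labels, (a, b))
        if sel.sum() < 20 or len(np.unique(fm.labels[sel])) < 2:
            continue
        res = train_eval_svm(
            fm.values[sel], fm.labels[sel], subjects=fm.subjects[sel],
            scheme=config.decode.scheme, n_splits=config.decode.n_splits,
            k_grid=tuple(config.decode.k_grid), seed=config.seed,
        )
        rows.append({"pair": pair, "scheme": res.scheme, "accuracy_pct": res.accuracy,
                     "kappa": res.kappa, "auc": res.auc, "best_k": res.best_k,
                     "confusion": res.confusion.tolist()})
        if res.per_subject is not None:
            res.per_subject.to_csv(outdir / f"decoding_{pair}_per_subject.csv", index=False)
    pd.DataFrame(rows).to_csv(outdir / "decoding.csv", index=False)
    (outdir / "decoding.json").write_text(json.dumps(rows, indent=2))
    report["stages"]["decode"] = {"pairs": [r["pair"] for r in rows],
                                  "n_in": clean.n_trials}


def _stage_connectivity(config: PipelineConfig, clean: TrialSet, outdir: Path,
                        report: dict) -> None:
    c = config.connectivity
    sub = clean.select(label="HN") if (clean.labels == "HN").sum() >= 2 else clean
    onset = int(sub.onset_idx[0])
    trace = sliding_correlation(sub.signals[:, 0], sub.signals[:, 1], sub.fs,
                                window_ms=c.window_ms, step_ms=c.step_ms,
                                onset_idx=onset)
    pd.DataFrame({"time_s": trace.times, "pcc_mean": trace.mean,
                  "pcc_sem": trace.sem}).to_csv(outdir / "correlation_trace.csv",
                                                index=False)
    lag = estimate_interhemispheric_lag(sub, max_lag_ms=c.max_lag_ms)
    (outdir / "lag.json").write_text(json.dumps(
        {"lag_ms": lag.lag_ms, "peak_r": lag.peak_r, "reliable": lag.reliable}))
    freqs = default_freqs(c.plv_n_freqs)
    plv = plv_timefreq(sub.signals[:, 0], sub.signals[:, 1], sub.fs, freqs,
                       window_ms=c.window_ms, step_ms=c.step_ms, onset_idx=onset)
    import h5py

    with h5py.File(outdir / "plv.h5", "w") as f:
        f.create_dataset("times", data=plv.times)
        f.create_dataset("freqs", data=plv.freqs)
        f.create_dataset("plv", data=plv.plv)
        if plv.plv_norm is not None:
            f.create_dataset("plv_norm", data=plv.plv_norm)
        f.attrs["window_ms"] = plv.window_ms
        f.attrs["n_trials"] = plv.n_trials
    report["stages"]["connectivity"] = {"n_in": sub.n_trials, "lag_ms": lag.lag_ms}
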