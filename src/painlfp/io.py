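"""On-disk interchange: the package HDF5 trial container, the events CSV,
and (optionally, via mne) EDF reading of continuous recordings.

Container schema v1:
    /signals        float64 (n_trials, 2, n_samples)
    /labels         fixed-width strings
    /onset_idx      int64
    /withdrawal_ms  float64 (NaN where absent)
    /session, /subject  fixed-width strings
    attrs: fs, schema_version, seed (optional)
Generator ground truth, when present, lives under /ground_truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import VALID_LABELS, TrialSet
from .errors import SchemaError

SCHEMA_VERSION = "1"

EVENT_COLUMNS = ("trial_id", "subject", "session", "label", "onset_s", "withdrawal_ms")


def save_trialset(trial_set: TrialSet, path: str | Path) -> None:
    """Write a TrialSet (and any array-valued ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=trial_set.signals)
        f.create_dataset("labels", data=trial_set.labels.astype("S4"))
        f.create_dataset("onset_idx", data=trial_set.onset_idx)
        f.create_dataset("withdrawal_ms", data=trial_set.withdrawal_ms)
        f.create_dataset("session", data=trial_set.session.astype("S32"))
        f.create_dataset("subject", data=trial_set.subject.astype("S32"))
        f.attrs["fs"] = trial_set.fs
        f.attrs["schema_version"] = SCHEMA_VERSION
        if "seed" in trial_set.meta:
            f.attrs["seed"] = int(trial_set.meta["seed"])
        gt = f.create_group("ground_truth")
        for key in ("templates", "coupling"):
            if key in trial_set.meta:
                grp = gt.create_group(key)
                for name, arr in trial_set.meta[key].items():
                    grp.create_dataset(name, data=np.asarray(arr))
        if "artifact_trials" in trial_set.meta:
            gt.create_dataset("artifact_trials",
                              data=np.asarray(trial_set.meta["artifact_trials"], dtype=int))


def load_trialset(path: str | Path) -> TrialSet:
    with h5py.File(path, "r") as f:
        _check_schema(f)
        meta: dict = {}
        if "seed" in f.attrs:
            meta["seed"] = int(f.attrs["seed"])
        if "ground_truth" in f:
            gt = f["ground_truth"]
            for key in ("templates", "coupling"):
                if key in gt:
                    meta[key] = {k: gt[key][k][()] for k in gt[key]}
            if "artifact_trials" in gt:
                meta["artifact_trials"] = gt["artifact_trials"][()]
        return TrialSet(
            f["signals"][()],
            float(f.attrs["fs"]),
            f["onset_idx"][()],
            f["labels"][()].astype("U4"),
            f["withdrawal_ms"][()],
            f["session"][()].astype("U32"),
            f["subject"][()].astype("U32"),
            meta,
        )


def _check_schema(f: h5py.File) -> None:
    for ds in ("signals", "labels", "onset_idx", "withdrawal_ms", "session", "subject"):
        if ds not in f:
            raise SchemaError(f"container missing dataset /{ds}")
    if "fs" not in f.attrs:
        raise SchemaError("container missing fs attribute")
    if f["signals"].ndim != 3 or f["signals"].shape[1] != 2:
        raise SchemaError("signals must be (n_trials, 2, n_samples)")


def validate_container(path: str | Path) -> list[str]:
    """Human-readable diagnostics for a trial container; raises SchemaError
    on the first structural violation."""
    diags = []
    with h5py.File(path, "r") as f:
        _check_schema(f)
        n, _, ns = f["signals"].shape
        labels = f["labels"][()].astype("U4")
        bad = set(np.unique(labels)) - set(VALID_LABELS)
        if bad:
            raise SchemaError(f"labels outside {VALID_LABELS}: {sorted(bad)}")
        onsets = f["onset_idx"][()]
        if n and (onsets.min() < 0 or onsets.max() >= ns):
            raise SchemaError("onset indices outside the sample range")
        diags.append(f"schema version: {f.attrs.get('schema_version', '?')}")
        diags.append(f"fs: {float(f.attrs['fs'])} Hz")
        diags.append(f"trials: {n} x 2 hemispheres x {ns} samples")
        for lab in VALID_LABELS:
            diags.append(f"  {lab}: {int((labels == lab).sum())}")
        if not np.all(np.isfinite(f["signals"][()])):
            raise SchemaError("non-finite samples in /signals")
        diags.append("all samples finite")
    return diags


def events_table(trial_set: TrialSet) -> pd.DataFrame:
    """Per-trial events table (onset_s is relative to each epoch start)."""
    return pd.DataFrame(
        {
            "trial_id": np.arange(trial_set.n_trials),
            "subject": trial_set.subject,
            "session": trial_set.session,
            "label": trial_set.labels,
            "onset_s": trial_set.onset_idx / trial_set.fs,
            "withdrawal_ms": trial_set.withdrawal_ms,
        }
    )


def write_events_csv(trial_set: TrialSet, path: str | Path) -> None:
    events_table(trial_set).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(("label", "onset_s")) - set(df.columns)
    if missing:
        raise SchemaError(f"events CSV missing columns: {sorted(missing)}")
    return df


def read_edf(path: str | Path, channels: list[str] | None = None):
    """Load a continuous EDF recording via mne (optional dependency).

    Returns (data array (n_channels, n_samples), fs, channel names).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels:
        raw = raw.pick(channels)
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str))
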