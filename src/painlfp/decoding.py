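"""Stimulation-intensity decoding from band-limited amplitude features.

Features: per hemisphere and per canonical sub-band (theta .. high-gamma,
zero-phase Butterworth band-pass), the mean absolute value (MAV) in 30-ms
non-overlapping windows over the 3-s post-stimulus interval - 2 x 5 x 100
= 1000 features per bilateral trial.  Features are z-scored, ranked by
minimum-redundancy-maximum-relevance (mRMR) mutual information, and fed to
a Gaussian-kernel SVM evaluated by stratified k-fold or
leave-one-subject-out validation.  Feature selection and normalization are
fitted inside each training fold only (no leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold
from sklearn.svm import SVC

from .datatypes import BANDS, TrialSet
from .errors import InvalidArgumentError
from .preprocess import bandpass

_HEMI_NAMES = ("ipsi", "contra")


@dataclass
class FeatureMatrix:
    """Trials x features MAV matrix with per-column provenance."""

    values: np.ndarray
    provenance: pd.DataFrame      # columns: hemisphere, band, window, start_ms
    labels: np.ndarray
    subjects: np.ndarray

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureRanking:
    """Greedy mRMR ranking: selected indices in order with the objective
    value, relevance I(x; y), and mean redundancy at selection time."""

    order: np.ndarray
    objective: np.ndarray
    relevance: np.ndarray
    redundancy: np.ndarray


@dataclass
class ClassifierResult:
    scheme: str
    accuracy: float               # percent
    kappa: float
    auc: float
    confusion: np.ndarray
    best_k: int
    classes: tuple
    accuracy_per_k: dict = field(default_factory=dict)
    per_subject: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_mav_features(trial_set: TrialSet, bands=BANDS, window_ms: float = 30.0,
                         interval_s: tuple[float, float] = (0.0, 3.0),
                         order: int = 4, filter_bands: bool = True) -> FeatureMatrix:
    """Band-limited MAV features on the post-stimulus interval.

    ``filter_bands=False`` skips the band-pass (every band sees the raw
    signal) - a bypass used for arithmetic checks only.
    """
    fs = trial_set.fs
    w = int(round(window_ms / 1000.0 * fs))
    if w < 1:
        raise InvalidArgumentError("window too short")
    on = trial_set.onset_idx
    a = (on + int(round(interval_s[0] * fs)))
    b = (on + int(round(interval_s[1] * fs)))
    if np.any(a < 0) or np.any(b > trial_set.n_samples):
        raise InvalidArgumentError("feature interval outside the epoch")
    seg_len = int(b[0] - a[0])
    n_windows = seg_len // w
    if n_windows * w != seg_len:
        warnings.warn("interval not divisible by the window; trailing partial window dropped")
    # gather interval slice per trial (onsets may differ)
    X = np.stack([trial_set.signals[i, :, a[i]:a[i] + n_windows * w]
                  for i in range(trial_set.n_trials)])
    cols = []
    prov = []
    for h, hemi in enumerate(_HEMI_NAMES):
        for band in bands:
            name, lo, hi = band
            xb = bandpass(X[:, h, :], fs, lo, hi, order) if filter_bands else X[:, h, :]
            mav = np.abs(xb).reshape(trial_set.n_trials, n_windows, w).mean(axis=2)
            cols.append(mav)
            for wi in range(n_windows):
                prov.append({"hemisphere": hemi, "band": name, "window": wi,
                             "start_ms": interval_s[0] * 1000.0 + wi * window_ms})
    values = np.concatenate(cols, axis=1)
    return FeatureMatrix(values, pd.DataFrame(prov), trial_set.labels.copy(),
                         trial_set.subject.copy())


def normalize_features(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scoring (sample sd).  Constant columns are dropped with a
    warning; returns (normalized matrix, indices of kept columns)."""
    X = np.asarray(values, dtype=float)
    if X.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 rows to normalize")
    sd = X.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    if len(keep) < X.shape[1]:
        warnings.warn(f"dropped {X.shape[1] - len(keep)} constant feature columns")
    Xn = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Xn, keep


# ---------------------------------------------------------------------------
# Mutual information and mRMR
# ---------------------------------------------------------------------------

def _discretize(X: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency discretization of each column into ``bins`` levels."""
    n = X.shape[0]
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    out = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        edges = np.quantile(X[:, j], qs)
        out[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return out


def _mi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def mutual_information_matrix(xd: np.ndarray, yd: np.ndarray, bins_x: int,
                              bins_y: int) -> np.ndarray:
    """Plug-in MI (nats) between every column of ``xd`` and the single
    discrete vector ``yd``, via one joint bincount per column."""
    n, m = xd.shape
    mis = np.empty(m)
    for j in range(m):
        joint = np.bincount(xd[:, j] * bins_y + yd, minlength=bins_x * bins_y)
        mis[j] = _mi_from_counts(joint.reshape(bins_x, bins_y))
    return mis


def mrmr_select(values: np.ndarray, labels: np.ndarray, k: int,
                bins: int = 8) -> FeatureRanking:
    """Greedy mRMR ranking of ``k`` features.

    Step j maximizes I(x; y) - (1/|S|) * sum_{s in S} I(x; x_s) with
    plug-in mutual information on equal-frequency discretized features
    (``bins`` levels).  The first pick is the maximally relevant feature.
    """
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if k <= 0:
        raise InvalidArgumentError("k must be positive")
    if X.ndim != 2:
        raise InvalidArgumentError("feature matrix must be 2-D")
    k = min(k, X.shape[1])
    classes, yd = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise InvalidArgumentError("need >= 2 classes")
    xd = _discretize(X, bins)
    relevance = mutual_information_matrix(xd, yd, bins, len(classes))

    m = X.shape[1]
    selected = np.empty(k, dtype=int)
    objective = np.empty(k)
    sel_relevance = np.empty(k)
    sel_redundancy = np.empty(k)
    red_sum = np.zeros(m)
    available = np.ones(m, dtype=bool)

    first = int(np.argmax(relevance))
    selected[0] = first
    objective[0] = relevance[first]
    sel_relevance[0] = relevance[first]
    sel_redundancy[0] = 0.0
    available[first] = False

    for step in range(1, k):
        last = selected[step - 1]
        red_sum += mutual_information_matrix(xd, xd[:, last], bins, bins)
        score = relevance - red_sum / step
        score[~available] = -np.inf
        nxt = int(np.argmax(score))
        selected[step] = nxt
        objective[step] = score[nxt]
        sel_relevance[step] = relevance[nxt]
        sel_redundancy[step] = red_sum[nxt] / step
        available[nxt] = False
    return FeatureRanking(selected, objective, sel_relevance, sel_redundancy)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e); 0 when p_e = 1."""
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise InvalidArgumentError("confusion matrix must be square")
    n = C.sum()
    po = np.trace(C) / n
    pe = float((C.sum(axis=0) * C.sum(axis=1)).sum()) / (n * n)
    if pe >= 1.0:
        return 0.0
    return float((po - pe) / (1.0 - pe))


def train_eval_svm(values: np.ndarray, labels: np.ndarray,
                   subjects: np.ndarray | None = None, scheme: str = "kfold",
                   n_splits: int = 10, k_grid: tuple[int, ...] = (25, 50, 100),
                   C_grid: tuple[float, ...] = (1.0, 10.0),
                   mi_bins: int = 8, inner_splits: int = 3,
                   class_weight: str | None = "balanced",
                   seed: int = 0) -> ClassifierResult:
    """Gaussian-kernel SVM with within-fold mRMR selection.

    For every outer fold: z-score and rank features on the training split
    only; for each candidate count in ``k_grid`` pick the SVM cost by a
    small inner cross-validated grid, then predict the test split.  The
    reported result uses the feature count with the best pooled accuracy.
    LOSO (``scheme='loso'``) additionally reports per-subject rows.
    """
    X = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InvalidArgumentError("decoding is defined for binary class pairs")
    k_grid = tuple(int(k) for k in k_grid)
    if scheme == "kfold":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
    elif scheme == "loso":
        if subjects is None or len(np.unique(subjects)) < 2:
            raise InvalidArgumentError("LOSO needs >= 2 subjects")
        splits = list(LeaveOneGroupOut().split(X, y, groups=subjects))
    else:
        raise InvalidArgumentError(f"unknown scheme {scheme!r}")

    n = len(y)
    preds = {k: np.full(n, -1, dtype=int) for k in k_grid}
    scores = {k: np.full(n, np.nan) for k in k_grid}
    evaluated = np.zeros(n, dtype=bool)
    y_idx = np.searchsorted(classes, y)

    for tr, te in splits:
        if len(np.unique(y[tr])) < 2:
            warnings.warn("fold with a single training class skipped")
            continue
        evaluated[te] = True
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        ranking = mrmr_select(Xtr, y[tr], max(k_grid), bins=mi_bins)
        for k in k_grid:
            cols = ranking.order[:k]
            best_c, best_acc = C_grid[0], -1.0
            if len(C_grid) > 1:
                inner = StratifiedKFold(n_splits=inner_splits, shuffle=True,
                                        random_state=seed)
                for Cv in C_grid:
                    accs = []
                    for itr, ite in inner.split(Xtr[:, cols], y[tr]):
                        clf = SVC(kernel="rbf", C=Cv, gamma="scale",
                                  class_weight=class_weight)
                        clf.fit(Xtr[itr][:, cols], y[tr][itr])
                        accs.append(np.mean(clf.predict(Xtr[ite][:, cols]) == y[tr][ite]))
                    if np.mean(accs) > best_acc:
                        best_acc, best_c = float(np.mean(accs)), Cv
            clf = SVC(kernel="rbf", C=best_c, gamma="scale", class_weight=class_weight)
            clf.fit(Xtr[:, cols], y[tr])
            preds[k][te] = np.searchsorted(classes, clf.predict(Xte[:, cols]))
            scores[k][te] = clf.decision_function(Xte[:, cols])

    acc_per_k = {
        k: 100.0 * np.mean(preds[k][evaluated] == y_idx[evaluated]) for k in k_grid
    }
    best_k = max(acc_per_k, key=acc_per_k.get)
    pk = preds[best_k][evaluated]
    yk = y_idx[evaluated]
    conf = np.zeros((2, 2), dtype=int)
    np.add.at(conf, (yk, pk), 1)
    try:
        auc = float(roc_auc_score(yk, scores[best_k][evaluated]))
    except ValueError:
        auc = np.nan

    per_subject = None
    if scheme == "loso":
        rows = []
        for s in sorted(np.unique(subjects)):
            m = (subjects == s) & evaluated
            if not m.any():
                continue
            cs = np.zeros((2, 2), dtype=int)
            np.add.at(cs, (y_idx[m], preds[best_k][m]), 1)
            rows.append({"subject": s,
                         "accuracy": 100.0 * np.mean(preds[best_k][m] == y_idx[m]),
                         "kappa": cohens_kappa(cs),
                         "n_trials": int(m.sum())})
        per_subject = pd.DataFrame(rows)

    return ClassifierResult(scheme, acc_per_k[best_k], cohens_kappa(conf), auc,
                            conf, best_k, tuple(classes), acc_per_k, per_subject)


def feature_selection_map(order: np.ndarray, provenance: pd.DataFrame,
                          n_select: int | None = None) -> pd.DataFrame:
    """Counts of selected features per (band, time window) cell - the
    feature-distribution map over time and frequency.

    Returns a DataFrame indexed by band (canonical order) with one column
    per window index, pooled over hemispheres.
    """
    bands = [b[0] for b in BANDS]
    n_windows = int(provenance["window"].max()) + 1 if len(provenance) else 0
    counts = pd.DataFrame(0, index=bands, columns=range(n_windows))
    sel = order if n_select is None else order[:n_select]
    for idx in np.asarray(sel, dtype=int):
        row = provenance.iloc[idx]
        counts.loc[row["band"], row["window"]] += 1
    return counts
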