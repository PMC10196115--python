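"""Decoding tests: MAV feature identities, mRMR oracles, kappa arithmetic,
SVM evaluation bounds, and the no-leakage chance control."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from painlfp.datatypes import TrialSet
from painlfp.decoding import (
    cohens_kappa,
    extract_mav_features,
    feature_selection_map,
    mrmr_select,
    mutual_information_matrix,
    _discretize,
    normalize_features,
    train_eval_svm,
)
from painlfp.errors import InvalidArgumentError

FS = 1000.0


def _trialset(signals, labels, subjects=None, onset=0):
    n = signals.shape[0]
    return TrialSet(signals, FS, np.full(n, onset), np.array(labels),
                    np.full(n, np.nan), np.zeros(n, dtype=int),
                    np.array(subjects if subjects is not None else ["s0"] * n))


class TestMAVFeatures:
    def test_feature_count_identity(self, rng):
        ts = _trialset(rng.normal(size=(4, 2, 3000)), ["HN"] * 4)
        fm = extract_mav_features(ts)
        assert fm.values.shape == (4, 1000)
        assert (fm.provenance.groupby(["hemisphere", "band"]).size() == 100).all()

    def test_constant_signal_bypass(self):
        ts = _trialset(np.full((2, 2, 3000), -1.5), ["HN", "NN"])
        fm = extract_mav_features(ts, filter_bands=False)
        assert np.allclose(fm.values, 1.5)

    def test_sinusoid_mav_closed_form(self):
        # full periods of amplitude-A sine in each 30 ms window: MAV = 2A/pi
        a = 2.0
        t = np.arange(3000) / FS
        x = a * np.sin(2 * np.pi * (FS / 30.0) * t)  # one full period per window
        ts = _trialset(np.broadcast_to(x, (2, 2, 3000)).copy(), ["HN", "NN"])
        fm = extract_mav_features(ts, filter_bands=False)
        assert np.allclose(fm.values, 2 * a / np.pi, rtol=0.01)

    def test_provenance_windows_cover_interval(self, rng):
        ts = _trialset(rng.normal(size=(2, 2, 3000)), ["HN", "NN"])
        fm = extract_mav_features(ts)
        starts = fm.provenance.loc[fm.provenance.band == "theta", "start_ms"]
        assert starts.min() == 0.0 and starts.max() == 2970.0


class TestNormalize:
    def test_three_point_column(self):
        X, kept = normalize_features(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(X[:, 0], [-1.0, 0.0, 1.0])

    def test_columns_centered(self, rng):
        X, _ = normalize_features(rng.normal(3, 2, size=(50, 8)))
        assert np.abs(X.mean(axis=0)).max() < 1e-9

    def test_constant_column_dropped(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning):
            Xn, kept = normalize_features(X)
        assert list(kept) == [0, 2]


class TestMRMR:
    def test_label_copy_ranked_first(self, rng):
        y = rng.integers(0, 2, size=200)
        X = rng.normal(size=(200, 20))
        X[:, 7] = y + 0.01 * rng.normal(size=200)
        ranking = mrmr_select(X, y, k=5)
        assert ranking.order[0] == 7
        assert ranking.relevance[0] == ranking.relevance.max()

    def test_redundant_twin_ranked_after_weaker_independent(self, rng):
        n = 600
        y = rng.integers(0, 2, size=n)
        strong = y + 0.3 * rng.normal(size=n)
        weak = y + 1.2 * rng.normal(size=n)
        X = np.column_stack([strong, strong + 1e-3 * rng.normal(size=n), weak])
        ranking = mrmr_select(X, y, k=3)
        assert ranking.order[0] in (0, 1)          # a strong feature first
        assert ranking.order[1] == 2               # then the independent weak one
        assert ranking.order[2] in (0, 1)          # the redundant twin last

    def test_shuffled_labels_kill_relevance(self, rng):
        n = 300
        y = rng.integers(0, 2, size=n)
        X = np.column_stack([y + 0.2 * rng.normal(size=n)])
        xd = _discretize(X, 8)
        true_mi = mutual_information_matrix(xd, y, 8, 2)[0]
        null = [
            mutual_information_matrix(xd, rng.permutation(y), 8, 2)[0]
            for _ in range(100)
        ]
        shuffled_mi = mutual_information_matrix(xd, rng.permutation(y), 8, 2)[0]
        assert true_mi > np.quantile(null, 0.95)
        assert shuffled_mi < np.quantile(null, 0.99)

    def test_invalid_k(self, rng):
        with pytest.raises(InvalidArgumentError):
            mrmr_select(rng.normal(size=(20, 4)), rng.integers(0, 2, 20), k=0)


class TestKappa:
    def test_known_values(self):
        assert cohens_kappa([[50, 0], [0, 50]]) == 1.0
        assert cohens_kappa([[25, 25], [25, 25]]) == 0.0
        assert cohens_kappa([[40, 10], [20, 30]]) == pytest.approx(0.4)

    def test_matches_sklearn(self, rng):
        yt = rng.integers(0, 2, size=300)
        yp = np.where(rng.random(300) < 0.8, yt, 1 - yt)
        conf = np.zeros((2, 2), dtype=int)
        np.add.at(conf, (yt, yp), 1)
        assert cohens_kappa(conf) == pytest.approx(cohen_kappa_score(yt, yp))

    def test_degenerate_chance_agreement(self):
        assert cohens_kappa([[10, 0], [0, 0]]) == 0.0


class TestSVM:
    def _gaussians(self, rng, n=200, d=20, dprime=6.0):
        X = rng.normal(size=(n, d))
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        X[y == "B", 0] += dprime
        subj = np.tile(["r1", "r2", "r3", "r4"], n // 4)
        return X, y, subj

    def test_separable_classes_high_accuracy(self, rng):
        X, y, subj = self._gaussians(rng)
        res = train_eval_svm(X, y, subjects=subj, scheme="kfold", n_splits=5,
                             k_grid=(5,), seed=0)
        assert res.accuracy >= 95.0
        assert res.kappa > 0.9
        assert res.auc > 0.98
        assert res.confusion.sum() == len(y)

    def test_shuffled_labels_at_chance(self, rng):
        X, y, subj = self._gaussians(rng)
        ys = rng.permutation(y)
        res = train_eval_svm(X, ys, subjects=subj, scheme="kfold", n_splits=5,
                             k_grid=(5,), seed=0)
        # binomial 95% band around 50% for n = 200
        assert 50 - 7 <= res.accuracy <= 50 + 7

    def test_loso_reports_per_subject(self, rng):
        X, y, subj = self._gaussians(rng, n=120)
        res = train_eval_svm(X, y, subjects=subj, scheme="loso", k_grid=(5,))
        assert res.per_subject is not None
        assert set(res.per_subject.subject) == {"r1", "r2", "r3", "r4"}
        assert res.accuracy >= 90.0

    def test_multiclass_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array(["A", "B", "C"] * 10)
        with pytest.raises(InvalidArgumentError):
            train_eval_svm(X, y)


class TestFeatureMap:
    def _prov(self, n_windows=100):
        rows = []
        for hemi in ("ipsi", "contra"):
            for band in ("theta", "alpha", "beta", "low_gamma", "high_gamma"):
                for w in range(n_windows):
                    rows.append({"hemisphere": hemi, "band": band, "window": w,
                                 "start_ms": 30.0 * w})
        return pd.DataFrame(rows)

    def test_single_band_selection_single_row(self):
        prov = self._prov()
        theta_cols = prov.index[prov.band == "theta"][:10].to_numpy()
        counts = feature_selection_map(theta_cols, prov)
        assert counts.loc["theta"].sum() == 10
        assert counts.drop(index="theta").to_numpy().sum() == 0

    def test_empty_ranking_zero_map(self):
        counts = feature_selection_map(np.array([], dtype=int), self._prov())
        assert counts.to_numpy().sum() == 0
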