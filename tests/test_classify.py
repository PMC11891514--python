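import numpy as np
import pytest

from envtrack.classify import (
    FeatureMatrix, build_features, metrics, nested_cv_svm,
    shapley_attribution, _standardize,
)
from envtrack.config import FEATURE_BANDS
from envtrack.mi import TMIF

RATE = 128.0
LAGS = np.arange(-26, 65) * 1000.0 / RATE


def _tmif(values):
    return TMIF(LAGS, np.asarray(values, float), "multivariate", RATE)


def _features(n=16, seed=0, effect_band=None, effect_size=1.0):
    """Small synthetic feature set: per-band TMIF rows + age."""
    rng = np.random.default_rng(seed)
    labels = ["aphasia" if i < n // 2 else "control" for i in range(n)]
    band_tmifs = {}
    for band in FEATURE_BANDS:
        rows = []
        for i in range(n):
            row = rng.standard_normal(LAGS.size) * 0.1 + 1.0
            if band == effect_band and labels[i] == "aphasia":
                row -= effect_size
            rows.append(_tmif(row))
        band_tmifs[band] = rows
    ages = list(rng.uniform(55, 85, n))
    return build_features(band_tmifs, ages), labels


class TestBuildFeatures:
    def test_column_bookkeeping(self):
        feats, _ = _features(8)
        n_nonneg = int(np.sum(LAGS >= 0))  # 65 lags at 128 Hz in [0, 500] ms
        assert n_nonneg == 65
        assert feats.X.shape == (8, 5 * 65 + 1)
        assert feats.columns[-1] == ("age", None)
        assert feats.prune_mask(200.0).sum() == 5 * int(np.sum((LAGS >= 0) & (LAGS <= 200))) + 1

    def test_identical_subjects_identical_rows(self):
        tm = _tmif(np.linspace(0, 1, LAGS.size))
        feats = build_features({b: [tm, tm] for b in FEATURE_BANDS}, [70.0, 70.0])
        np.testing.assert_array_equal(feats.X[0], feats.X[1])

    def test_inconsistent_lag_grids_rejected(self):
        a = _tmif(np.zeros(LAGS.size))
        b = TMIF(LAGS[:-1], np.zeros(LAGS.size - 1), "multivariate", RATE)
        with pytest.raises(ValueError, match="lag grids"):
            build_features({band: [a, b] for band in FEATURE_BANDS}, [70.0, 71.0])

    def test_standardization_is_fold_local(self, rng):
        train = rng.standard_normal((10, 4)) + 5.0
        test = rng.standard_normal((3, 4)) + 5.0
        tr, te = _standardize(train, test)
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-12)
        # test-fold columns are standardized with training parameters only
        assert np.max(np.abs(te.mean(axis=0))) > 1e-6


class TestMetrics:
    def test_clinical_confusion_matrix_arithmetic(self):
        # 26 aphasia (TP=23, FN=3), 22 controls (TN=17, FP=5)
        y_true = np.array([1] * 26 + [0] * 22)
        y_pred = np.array([1] * 23 + [0] * 3 + [0] * 17 + [1] * 5)
        dec = np.where(y_pred == 1, 1.0, -1.0)
        rep = metrics(y_true, y_pred, dec)
        assert rep.sensitivity == pytest.approx(23 / 26)
        assert round(100 * rep.sensitivity, 2) == 88.46
        assert rep.specificity == pytest.approx(17 / 22)
        assert round(100 * rep.specificity, 2) == 77.27
        assert rep.accuracy == pytest.approx(40 / 48)

    def test_all_correct(self):
        y = np.array([0, 1, 0, 1])
        rep = metrics(y, y, np.array([-1.0, 2.0, -3.0, 4.0]))
        assert (rep.accuracy, rep.f1, rep.auc, rep.sensitivity, rep.specificity) \
            == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_constant_decision_values_give_chance_auc(self):
        y = np.array([0, 1, 0, 1])
        rep = metrics(y, np.array([1, 1, 0, 0]), np.zeros(4))
        assert rep.auc == pytest.approx(0.5)

    def test_roc_monotone(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        dec = rng.standard_normal(40)
        rep = metrics(y, (dec > 0).astype(int), dec)
        roc = np.asarray(rep.roc)
        assert np.all(np.diff(roc[:, 0]) >= 0) and np.all(np.diff(roc[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            metrics(np.ones(4, dtype=int), np.ones(4, dtype=int), np.ones(4))


class TestNestedCV:
    def test_separable_features_classified_perfectly(self):
        feats, labels = _features(16, seed=1, effect_band="theta", effect_size=3.0)
        rep = nested_cv_svm(feats, labels, seed=0)
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_deterministic(self):
        feats, labels = _features(14, seed=2, effect_band="delta", effect_size=0.4)
        r1 = nested_cv_svm(feats, labels, seed=3)
        r2 = nested_cv_svm(feats, labels, seed=3)
        assert r1.accuracy == r2.accuracy
        assert [p["decision"] for p in r1.predictions] == \
            [p["decision"] for p in r2.predictions]

    def test_chosen_params_recorded_per_fold(self):
        feats, labels = _features(14, seed=4, effect_band="theta", effect_size=2.0)
        rep = nested_cv_svm(feats, labels, seed=0,
                            c_grid=(0.1, 1.0), prune_grid_ms=(200.0, 500.0))
        assert len(rep.chosen_params) == 14
        assert all(p["C"] in (0.1, 1.0) and p["prune_ms"] in (200.0, 500.0)
                   for p in rep.chosen_params)

    def test_too_few_subjects_rejected(self):
        feats, labels = _features(8, seed=5)
        with pytest.raises(ValueError, match="per class"):
            nested_cv_svm(feats, labels)

    def test_outlier_in_held_out_subject_cannot_leak(self):
        """Leakage canary: an absurd artifact injected into a held-out
        subject must not change anything learned from that subject's
        training fold (inner-CV accuracy over the remaining subjects)."""
        feats, labels = _features(14, seed=6, effect_band="theta", effect_size=2.0)
        rep1 = nested_cv_svm(feats, labels, seed=0, c_grid=(0.5, 2.0),
                             prune_grid_ms=(300.0, 500.0))
        X2 = feats.X.copy()
        X2[0] += 1e3  # absurd artifact in subject 0
        feats2 = FeatureMatrix(X2, feats.columns, feats.subject_ids)
        rep2 = nested_cv_svm(feats2, labels, seed=0, c_grid=(0.5, 2.0),
                             prune_grid_ms=(300.0, 500.0))
        # fold 0 trains on subjects 1..13, which are identical in both runs
        assert rep2.chosen_params[0] == rep1.chosen_params[0] or \
            rep2.chosen_params[0]["inner_accuracy"] == rep1.chosen_params[0]["inner_accuracy"]
        assert rep2.chosen_params[0]["inner_accuracy"] == \
            rep1.chosen_params[0]["inner_accuracy"]


class TestShapley:
    @staticmethod
    def _linear_model(weights):
        w = np.asarray(weights, dtype=float)
        return lambda Z: Z @ w

    def test_ignored_group_gets_zero_attribution(self, rng):
        X = rng.standard_normal((6, 4))
        bg = rng.standard_normal((8, 4))
        groups = {"used": np.array([0, 1]), "ignored": np.array([2, 3])}
        att = shapley_attribution(self._linear_model([1.0, -2.0, 0.0, 0.0]),
                                  X, groups, bg)
        assert np.max(np.abs(att.values[:, att.group_names.index("ignored")])) < 1e-9

    def test_single_group_gets_full_decision(self, rng):
        X = rng.standard_normal((5, 2))
        bg = rng.standard_normal((7, 2))
        att = shapley_attribution(self._linear_model([0.7, -0.3]), X,
                                  {"all": np.array([0, 1])}, bg)
        np.testing.assert_allclose(att.values[:, 0], att.decisions - att.baseline,
                                   atol=1e-12)

    def test_additivity(self, rng):
        X = rng.standard_normal((6, 6))
        bg = rng.standard_normal((10, 6))
        groups = {f"g{i}": np.array([2 * i, 2 * i + 1]) for i in range(3)}
        model = self._linear_model(rng.standard_normal(6))
        att = shapley_attribution(model, X, groups, bg)
        np.testing.assert_allclose(att.values.sum(axis=1),
                                   att.decisions - att.baseline, atol=1e-10)

    def test_dominant_group_ranks_first(self, rng):
        X = rng.standard_normal((10, 4))
        bg = rng.standard_normal((10, 4))
        att = shapley_attribution(self._linear_model([5.0, 0.1, 0.1, 0.1]), X,
                                  {"big": np.array([0]), "s1": np.array([1]),
                                   "s2": np.array([2]), "s3": np.array([3])}, bg)
        assert att.ranking()[0] == "big"

    def test_empty_background_rejected(self, rng):
        with pytest.raises(ValueError):
            shapley_attribution(self._linear_model([1.0]), rng.random((2, 1)),
                                {"a": np.array([0])}, np.empty((0, 1)))
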