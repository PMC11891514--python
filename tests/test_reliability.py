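import numpy as np
import pytest

from envtrack.mi import TMIF, compute_tmif
from envtrack.reliability import (
    StabilityCurve, between_subject_stability, bonferroni_correction,
    crop_and_tmif, fisher_z_compare, holm_correction, icc_oneway, knee_point,
    split_half_icc, split_half_mean_mi, within_subject_stability,
)

RATE = 128.0


# ---------------------------------------------------------------------------
# independent Kneedle oracle (deliberately written from the definition,
# not shared with the implementation)
# ---------------------------------------------------------------------------

def kneedle_oracle(x, y, s=1.0):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xn = (x - x.min()) / (x.max() - x.min())
    yn = (y - y.min()) / (y.max() - y.min())
    d = yn - xn
    candidates = []
    for i in range(1, len(d) - 1):
        if d[i] > d[i - 1] and d[i] >= d[i + 1]:
            candidates.append(i)
    if not candidates:
        return None
    step = s * np.mean(np.diff(xn))
    for ci, i in enumerate(candidates):
        nxt = candidates[ci + 1] if ci + 1 < len(candidates) else len(d)
        thresh = d[i] - step
        if any(d[j] < thresh for j in range(i + 1, nxt)):
            return x[i]
        if nxt == len(d) and d[i] >= d.max() - 1e-12:
            return x[i]
    return x[candidates[0]]


class TestICC:
    def test_hand_computed_oneway_anova(self):
        # 5 targets x 2 raters, worked by the one-way ANOVA formulas
        Y = np.array([[1.0, 2.0], [3.0, 2.5], [5.0, 6.0], [7.0, 6.5], [9.0, 10.0]])
        n, k = Y.shape
        grand = Y.mean()
        msb = k * np.sum((Y.mean(axis=1) - grand) ** 2) / (n - 1)
        msw = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2) / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        res = icc_oneway(Y)
        assert res.icc == pytest.approx(float(expected), abs=1e-12)
        assert res.ci[0] <= res.icc <= res.ci[1]

    def test_matches_pingouin_icc1(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        subj_effect = rng.normal(0, 2.0, 12)
        Y = subj_effect[:, None] + rng.normal(0, 0.8, (12, 2))
        res = icc_oneway(Y)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile([0, 1], 12),
            "scores": Y.ravel(),
        })
        table = pg.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="scores")
        pg_row = table.iloc[0]  # one-way random effects, single rater
        assert "1" in str(pg_row["Type"])
        assert res.icc == pytest.approx(pg_row["ICC"], abs=1e-9)
        assert res.p_value == pytest.approx(pg_row["pval"], abs=1e-9)
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        assert res.ci[0] == pytest.approx(pg_row[ci_col][0], abs=5e-3)
        assert res.ci[1] == pytest.approx(pg_row[ci_col][1], abs=5e-3)

    def test_identical_raters_give_one(self):
        x = np.arange(6, dtype=float)
        res = icc_oneway(np.column_stack([x, x]))
        assert res.icc == 1.0 and res.ci[1] == 1.0

    def test_independent_noise_near_zero(self, rng):
        vals = [icc_oneway(rng.standard_normal((30, 2))).icc for _ in range(100)]
        assert abs(np.mean(vals)) < 0.1

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway(np.ones((5, 2)))


class TestCorrections:
    def test_holm_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 0.2, 9)
        ours = holm_correction(p)
        theirs = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_bonferroni(self):
        np.testing.assert_allclose(bonferroni_correction(np.array([0.01, 0.4])),
                                   [0.02, 0.8])

    def test_fisher_z_equal_coefficients(self):
        z, p = fisher_z_compare(0.8, 20, 0.8, 25)
        assert z == 0.0 and p == 1.0
        z2, p2 = fisher_z_compare(0.95, 20, 0.2, 20)
        assert p2 < 0.01


class TestKneePoint:
    @pytest.mark.parametrize("curve", [
        lambda x: 1 - np.exp(-x / 4.0),
        lambda x: x / (x + 3.0),
        lambda x: np.log1p(x),
    ])
    def test_matches_independent_kneedle_oracle(self, curve):
        x = np.arange(1, 26, 2, dtype=float)
        y = curve(x)
        ours = knee_point(x, y)
        oracle = kneedle_oracle(x, y)
        assert ours.found and oracle is not None
        assert ours.knee == oracle

    def test_linear_curve_has_no_knee(self):
        x = np.arange(1, 26, 2, dtype=float)
        res = knee_point(x, 0.5 * x)
        assert not res.found and res.knee == x[-1]

    def test_step_curve_knee_at_step(self):
        x = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        y = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        res = knee_point(x, y)
        assert res.found and res.knee == 5.0

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            knee_point(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestCropping:
    def test_grid_and_identity(self, noise_eeg_theta, theta_envelope):
        crops = crop_and_tmif(noise_eeg_theta, theta_envelope, [0.5, 1.0])
        assert set(crops) == {0.5, 1.0}
        full = compute_tmif(noise_eeg_theta, theta_envelope)
        full_again = crop_and_tmif(noise_eeg_theta, theta_envelope, [1.0])[1.0]
        np.testing.assert_allclose(full_again.mi, full.mi, atol=1e-12)

    def test_too_long_crop_rejected(self, noise_eeg_theta, theta_envelope):
        with pytest.raises(ValueError, match="exceeds"):
            crop_and_tmif(noise_eeg_theta, theta_envelope, [99.0])


class TestStability:
    def _fake_tmif(self, values):
        lags = np.arange(len(values)) * 1000.0 / RATE
        return TMIF(lags, np.asarray(values, float), "multivariate", RATE)

    def test_within_subject_is_one_at_full_duration(self, rng):
        full = [self._fake_tmif(rng.random(40)) for _ in range(4)]
        cropped = {"theta": {1.0: [self._fake_tmif(t.mi + 0.1 * rng.random(40))
                                   for t in full],
                             5.0: full}}
        curves = within_subject_stability(cropped, {"theta": full})
        assert curves["theta"].values[-1] == pytest.approx(1.0)
        assert curves["average"].values[-1] == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero_icc(self, rng):
        full = [self._fake_tmif(rng.standard_normal(50)) for _ in range(50)]
        cropped = {"theta": {1.0: [self._fake_tmif(rng.standard_normal(50))
                                   for _ in range(50)]}}
        curves = within_subject_stability(cropped, {"theta": full})
        assert abs(curves["theta"].values[0]) < 0.1

    def test_between_subject_permutation_destroys_icc(self, rng):
        strengths = np.linspace(0.1, 2.0, 12)
        full = strengths + 0.01 * rng.standard_normal(12)
        cropped = strengths + 0.05 * rng.standard_normal(12)
        curves = between_subject_stability(
            {"theta": {3.0: cropped}}, {"theta": full})
        high = curves["theta"].values[0]
        permuted = between_subject_stability(
            {"theta": {3.0: rng.permutation(cropped)}}, {"theta": full})
        assert high > 0.9
        assert permuted["theta"].values[0] < high - 0.5

    def test_performance_vs_time_improves_with_duration(self):
        """Classifier accuracy per duration: noise-dominated at the shortest
        crop, separable at the longest; the curve records all three metrics
        and a knee on the grid."""
        from envtrack.classify import build_features
        from envtrack.config import FEATURE_BANDS
        from envtrack.reliability import performance_vs_time

        rng = np.random.default_rng(8)
        n = 14
        labels = ["aphasia" if i < 7 else "control" for i in range(n)]
        lags = np.arange(-26, 65) * 1000.0 / RATE
        by_duration = {}
        for minutes, effect in [(1.0, 0.0), (3.0, 1.0), (5.0, 2.0)]:
            band_tmifs = {}
            for band in FEATURE_BANDS:
                rows = []
                for i in range(n):
                    row = rng.standard_normal(lags.size) * 0.3 + 1.0
                    if band == "theta" and labels[i] == "aphasia":
                        row -= effect
                    rows.append(TMIF(lags, row, "multivariate", RATE))
                band_tmifs[band] = rows
            by_duration[minutes] = build_features(band_tmifs,
                                                  list(rng.uniform(60, 80, n)))
        curve = performance_vs_time(by_duration, labels, seed=0,
                                    c_grid=(1.0,), prune_grid_ms=(500.0,))
        assert curve.curve_kind == "svm_performance"
        assert curve.values[-1] > curve.values[0]
        assert curve.values[-1] == 1.0  # fully separable at the longest crop
        assert curve.knee_minutes in (1.0, 3.0, 5.0)
        assert set(curve.extras) == {"f1", "auc"}

    def test_single_duration_knee_is_that_duration(self):
        curve = StabilityCurve([5.0], [0.8], "svm_performance").detect_knee()
        assert curve.knee_minutes == 5.0 and curve.knee_found

    def test_minutes_must_increase(self):
        with pytest.raises(ValueError):
            StabilityCurve([5.0, 3.0], [0.1, 0.2], "within_subject")


class TestSplitHalf:
    def test_identical_halves_give_one(self):
        mat = np.column_stack([np.arange(6.0), np.arange(6.0)])
        rep = split_half_icc({"theta": {"control": mat}})
        row = rep.table.iloc[0]
        assert row["icc"] == 1.0 and row["ci_high"] == 1.0

    def test_hand_computed_toy_table(self):
        Y = np.array([[1.0, 1.2], [2.0, 2.1], [3.0, 2.7], [4.0, 4.4],
                      [5.0, 5.1], [6.0, 5.6]])
        rep = split_half_icc({"theta": {"control": Y}})
        expected = icc_oneway(Y)
        row = rep.table.iloc[0]
        assert row["icc"] == pytest.approx(expected.icc)
        assert row["p"] == pytest.approx(expected.p_value)

    def test_noise_halves_distributed_around_zero(self, rng):
        vals = []
        for _ in range(100):
            rep = split_half_icc({"theta": {"control": rng.standard_normal((10, 2))}})
            vals.append(rep.table.iloc[0]["icc"])
        assert abs(np.mean(vals)) < 0.1

    def test_group_comparison_and_correction(self, rng):
        halves = {}
        for band in ("delta", "theta"):
            strengths = rng.uniform(0.5, 2.0, 8)
            mat = np.column_stack([strengths, strengths + 0.1 * rng.standard_normal(8)])
            halves[band] = {"control": mat, "aphasia": mat + 0.05}
        rep = split_half_icc(halves)
        assert set(rep.fisher["band"]) == {"delta", "theta"}
        assert (rep.table["p_corrected"] >= rep.table["p"] - 1e-15).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            split_half_icc({"theta": {"control": np.zeros((2, 2))}})

    def test_split_half_mean_mi_runs(self, noise_eeg_theta, theta_envelope):
        a, b = split_half_mean_mi(noise_eeg_theta, theta_envelope)
        assert np.isfinite(a) and np.isfinite(b) and a >= 0 and b >= 0
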