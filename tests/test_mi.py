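import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri

from envtrack.envelope import BandEnvelope
from envtrack.mi import (
    TMIF, WindowMIEngine, _tmif_fast, _tmif_naive, compute_tmif,
    copula_gaussianize, gaussian_kernel, gaussian_mi, mean_mi, peak_mi,
    smooth_tmif,
)
from envtrack.preprocess import EEGBand

RATE = 128.0


def _band(data, names=None):
    data = np.atleast_2d(data)
    names = names or [f"ch{i}" for i in range(data.shape[0])]
    return EEGBand(data, RATE, "theta", names)


def _env(x):
    return BandEnvelope(x, RATE, "theta", (4.0, 8.0))


class TestCopula:
    def test_three_point_example(self):
        out = copula_gaussianize(np.array([3.0, 1.0, 2.0]))
        expected = ndtri(np.array([3, 1, 2]) / 4.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert abs(out[0] - 0.6745) < 1e-4 and abs(out[2]) < 1e-12

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.standard_normal(500)
        a = copula_gaussianize(x)
        np.testing.assert_array_equal(a, copula_gaussianize(x ** 3))
        np.testing.assert_array_equal(a, copula_gaussianize(np.exp(x)))

    def test_standard_normal_large_sample_nearly_identity(self, rng):
        x = rng.standard_normal(10_000)
        g = copula_gaussianize(x)
        assert np.corrcoef(x, g)[0, 1] > 0.999

    def test_marginal_is_standard_normal(self, rng):
        from scipy.stats import kstest

        g = copula_gaussianize(rng.exponential(size=2000))
        assert kstest(g, "norm").statistic < 0.05

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            copula_gaussianize(np.ones(10))
        with pytest.raises(ValueError, match="NaN"):
            copula_gaussianize(np.array([1.0, np.nan, 2.0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=60, unique=True))
    def test_output_strictly_monotone_in_input(self, values):
        x = np.array(values)
        g = copula_gaussianize(x)
        order = np.argsort(x)
        assert np.all(np.diff(g[order]) > 0)


class TestGaussianMI:
    def test_independent_near_zero(self, rng):
        x, y = rng.standard_normal((2, 10_000))
        assert gaussian_mi(copula_gaussianize(x), copula_gaussianize(y)) < 0.01

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.9])
    def test_matches_closed_form(self, rho, rng):
        n = 50_000
        ests = []
        for _ in range(4):  # average replicates to tame Monte-Carlo noise
            z = rng.standard_normal((n, 2))
            x = z[:, 0]
            y = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
            ests.append(gaussian_mi(copula_gaussianize(x), copula_gaussianize(y)))
        assert abs(np.mean(ests) - (-0.5 * np.log2(1 - rho ** 2))) < 0.01

    def test_symmetric_in_arguments(self, rng):
        x = rng.standard_normal((2000, 2))
        y = x @ [[0.4], [0.2]] + 0.5 * rng.standard_normal((2000, 1))
        gx, gy = copula_gaussianize(x), copula_gaussianize(y)
        assert abs(gaussian_mi(gx, gy) - gaussian_mi(gy, gx)) < 1e-12

    def test_linear_channel_mi_grows_as_noise_shrinks(self, rng):
        x = rng.standard_normal((20_000, 2))
        vals = []
        for noise in (1.0, 0.5, 0.1):
            y = x.sum(axis=1) + noise * rng.standard_normal(20_000)
            vals.append(gaussian_mi(copula_gaussianize(x), copula_gaussianize(y)))
        assert vals[0] < vals[1] < vals[2]

    def test_nonnegative_and_errors(self, rng):
        x = rng.standard_normal(50)
        assert gaussian_mi(copula_gaussianize(x),
                           copula_gaussianize(rng.standard_normal(50))) >= 0.0
        with pytest.raises(ValueError):
            gaussian_mi(np.zeros((10, 1)), np.zeros((12, 1)))


class TestTMIF:
    def test_fast_equals_naive_reference(self, rng):
        eeg = rng.standard_normal((3, 600))
        env = rng.standard_normal(600) + 0.4 * np.roll(eeg[1], -7)
        taus = np.arange(-12, 20)
        for variant in ("multivariate", "single_channel"):
            fast = _tmif_fast(eeg, env, taus, variant)
            naive = _tmif_naive(eeg, env, taus, variant)
            np.testing.assert_allclose(fast, naive, atol=1e-10)

    def test_delayed_envelope_recovers_latency(self, rng):
        n = 4000
        env = rng.standard_normal(n)
        delay = int(round(170 * RATE / 1000.0))  # samples
        eeg = np.roll(env, delay) + 0.01 * rng.standard_normal(n)
        tm = compute_tmif(_band(eeg), _env(env), (-200, 500), "single_channel")
        peak_lag = tm.lags_ms[np.argmax(tm.mi[0])]
        assert abs(peak_lag - 170.0) <= 2 * 1000.0 / RATE

    def test_monotone_marginal_transform_invariance(self, rng):
        eeg = rng.standard_normal((2, 800))
        env = rng.standard_normal(800) + 0.3 * eeg[0]
        base = compute_tmif(_band(eeg), _env(env)).mi
        cubed = compute_tmif(_band(eeg ** 3), _env(env)).mi
        exp_env = compute_tmif(_band(eeg), _env(np.exp(env))).mi
        np.testing.assert_allclose(base, cubed, atol=1e-9)
        np.testing.assert_allclose(base, exp_env, atol=1e-9)

    def test_affine_channel_rescaling_invariance(self, rng):
        eeg = rng.standard_normal((2, 800))
        env = rng.standard_normal(800) + 0.3 * eeg[0]
        base = compute_tmif(_band(eeg), _env(env)).mi
        scaled = compute_tmif(_band(eeg * np.array([[5.0], [-0.2]]) + 7.0), _env(env)).mi
        np.testing.assert_allclose(base, scaled, atol=1e-9)

    def test_multivariate_dominates_best_channel(self, rng):
        n = 50_000
        eeg = rng.standard_normal((3, n))
        env = 0.5 * eeg[0] + 0.3 * eeg[2] + rng.standard_normal(n)
        taus = (-26, 65)
        multi = compute_tmif(_band(eeg), _env(env), (0, 60), "multivariate").mi
        single = compute_tmif(_band(eeg), _env(env), (0, 60), "single_channel").mi
        assert np.all(multi >= single.max(axis=0) - 0.01)

    def test_global_copula_option(self, rng):
        """The flagged single-gaussianization variant is close to (but not
        identical with) the per-lag default on stationary data."""
        eeg = rng.standard_normal((2, 900))
        env = rng.standard_normal(900) + 0.4 * eeg[0]
        per_lag = compute_tmif(_band(eeg), _env(env)).mi
        global_ = compute_tmif(_band(eeg), _env(env), per_lag=False).mi
        assert np.all(global_ >= 0)
        assert np.corrcoef(per_lag, global_)[0, 1] > 0.95

    def test_nonnegative_everywhere(self, rng):
        tm = compute_tmif(_band(rng.standard_normal((2, 700))),
                          _env(rng.standard_normal(700)))
        assert np.all(tm.mi >= 0.0)

    def test_errors(self, rng):
        eeg, env = rng.standard_normal((2, 300)), rng.standard_normal(300)
        with pytest.raises(ValueError, match="equal durations"):
            compute_tmif(_band(eeg), _env(env[:200]))
        with pytest.raises(ValueError, match="lag exceeds"):
            compute_tmif(_band(eeg[:, :40]), _env(env[:40]), (-200, 500))
        with pytest.raises(ValueError, match="variant"):
            compute_tmif(_band(eeg), _env(env), variant="banana")

    def test_engine_matches_tmif_summary(self, rng):
        eeg = rng.standard_normal((3, 900))
        env = rng.standard_normal(900) + 0.2 * eeg[0]
        band = _band(eeg)
        engine = WindowMIEngine(band, (0.0, 400.0))
        tm = compute_tmif(band, _env(env), (-200, 500), "multivariate")
        assert engine.statistic(env, "mean_mi") == pytest.approx(
            mean_mi(tm, (0, 400)), abs=1e-12)
        assert engine.statistic(env, "peak_mi") == pytest.approx(
            peak_mi(tm, (0, 400)), abs=1e-12)


class TestSmoothingAndSummaries:
    def _tmif(self, mi):
        lags = np.arange(len(np.atleast_1d(mi))) * 1000.0 / RATE
        return TMIF(lags, np.asarray(mi, float), "multivariate", RATE)

    def test_kernel_is_normalized_nine_tap(self):
        w = gaussian_kernel()
        assert w.size == 9 and abs(w.sum() - 1.0) < 1e-12
        assert np.argmax(w) == 4

    def test_constant_unchanged(self):
        tm = self._tmif(np.full(40, 0.7))
        np.testing.assert_allclose(smooth_tmif(tm).mi, 0.7, atol=1e-12)

    def test_impulse_becomes_kernel(self):
        x = np.zeros(41)
        x[20] = 1.0
        sm = smooth_tmif(self._tmif(x)).mi
        np.testing.assert_allclose(sm[16:25], gaussian_kernel(), atol=1e-12)
        assert abs(sm.sum() - 1.0) < 1e-12

    def test_smoothing_never_increases_maximum(self, rng):
        tm = self._tmif(rng.random(60))
        assert smooth_tmif(tm).mi.max() <= tm.mi.max() + 1e-12

    def test_mean_mi_constant_and_window(self):
        tm = self._tmif(np.full(64, 0.3))
        assert mean_mi(tm, (0, 400)) == pytest.approx(0.3)
        assert mean_mi(tm, (0.0, tm.lags_ms[-1])) == pytest.approx(tm.mi.mean())
        with pytest.raises(ValueError, match="empty"):
            mean_mi(tm, (10_000.0, 20_000.0))
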