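import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import _oracles as orc
from arousalkit.features_time import (
    channel_stats,
    compute_time_features,
    cumulative_extrema,
    difference_stats,
    epoch_statistics,
    moving_median,
    raw_moments,
)
from arousalkit.signal_io import MultiChannelSignal, segment


class TestHandExamples:
    def test_raw_moments(self):
        assert raw_moments([1, 2, 3]) == (2.0, 1.0)
        mu, sigma = raw_moments([5.0] * 100)
        assert (mu, sigma) == (5.0, 0.0)

    def test_difference_stats_alternating_and_ramp(self):
        d, g, _, _ = difference_stats([0, 1, 0, 1, 0])
        assert (d, g) == (1.0, 0.0)
        d, g, _, _ = difference_stats([0, 1, 2, 3, 4])
        assert (d, g) == (1.0, 2.0)

    def test_difference_stats_normalised_identity(self, rng):
        x = rng.standard_normal(640)
        d, g, dn, gn = difference_stats(x)
        sigma = np.std(x, ddof=1)
        assert dn == pytest.approx(d / sigma, rel=1e-12)
        assert gn == pytest.approx(g / sigma, rel=1e-12)

    def test_cumulative_extrema(self):
        cmax, cmin = cumulative_extrema([3, 1, 4, 1, 5])
        np.testing.assert_array_equal(cmax, [3, 3, 4, 4, 5])
        np.testing.assert_array_equal(cmin, [3, 1, 1, 1, 1])

    def test_cumulative_extrema_monotone_input(self):
        x = np.arange(10.0)
        cmax, cmin = cumulative_extrema(x)
        np.testing.assert_array_equal(cmax, x)
        np.testing.assert_array_equal(cmin, np.zeros(10))

    def test_channel_stats_constant(self):
        with pytest.warns(UserWarning):  # zero-variance kurtosis
            s = channel_stats([4.0, 4.0, 4.0, 4.0])
        assert s["mav"] == 4.0
        assert s["rms"] == 4.0
        assert s["prms"] == 1.0
        assert s["maxmin"] == 0.0
        assert np.isnan(s["kurt"])

    def test_channel_stats_single_peak(self):
        s = channel_stats([0, 0, 10, 0, 0])
        assert s["pk"] == 10.0
        assert s["lpk"] == 3  # 1-based
        assert s["maxmin"] == 10.0
        assert s["pp"] == 2  # second largest at index 1 (earliest tie)

    def test_moving_median(self):
        np.testing.assert_array_equal(moving_median([1, 9, 1, 9, 1], 3), [1, 9, 1])
        x = [3.0, 1.0, 2.0]
        np.testing.assert_array_equal(moving_median(x, 1), x)
        with pytest.raises(ValueError):
            moving_median(x, 4)

    def test_epoch_statistics_hand(self):
        sig = MultiChannelSignal(np.array([[1.0], [2.0], [3.0], [4.0]]),
                                 fs=2.0, channel_names=["F3"])
        st_ = epoch_statistics(segment(sig, 2.0)[0])["F3"]
        assert st_.mean == 2.5
        assert st_.ptp == 3.0
        assert st_.argminim == 1 and st_.argmaxim == 4
        assert st_.var == pytest.approx(st_.std**2)

    def test_epoch_skewness_symmetric(self):
        stats = epoch_statistics(np.array([[-2.0], [-1.0], [0.0], [1.0], [2.0]]))
        assert stats["CH0"].skewness == pytest.approx(0.0, abs=1e-12)


class TestOracleAgreement:
    """Every operator matches an independent loop-based oracle."""

    N_WINDOWS = 50

    def _windows(self, rng):
        return rng.standard_normal((self.N_WINDOWS, 640)) * 30 + 5

    def test_time_features_match_loop_oracle(self, rng):
        for x in self._windows(rng):
            xs = list(x)
            f = compute_time_features(x)
            assert f.mu == pytest.approx(orc.mean(xs), rel=1e-12)
            assert f.sigma == pytest.approx(orc.sample_sd(xs), rel=1e-12)
            assert f.delta == pytest.approx(orc.mean_abs_first_diff(xs), rel=1e-12)
            assert f.gamma_diff == pytest.approx(orc.mean_abs_second_diff(xs), rel=1e-12)
            expected = orc.channel_stats(xs)
            for key, val in expected.items():
                assert getattr(f, key) == pytest.approx(val, rel=1e-12), key

    def test_cumulative_extrema_match_loop_oracle(self, rng):
        for x in self._windows(rng)[:10]:
            cmax, cmin = cumulative_extrema(x)
            np.testing.assert_allclose(cmax, orc.cumulative_max(list(x)), rtol=1e-15)
            np.testing.assert_allclose(cmin, orc.cumulative_min(list(x)), rtol=1e-15)

    def test_moving_median_matches_sort_oracle(self, rng):
        for x in self._windows(rng)[:5]:
            np.testing.assert_allclose(
                moving_median(x, 5), orc.moving_median(list(x), 5), rtol=1e-12)

    def test_epoch_statistics_match_loop_oracle(self, rng):
        for x in self._windows(rng)[:20]:
            stats = epoch_statistics(x[:, None])["CH0"]
            expected = orc.epoch_stats(list(x))
            for key, val in expected.items():
                assert getattr(stats, key) == pytest.approx(val, rel=1e-12), key

    def test_gaussian_kurtosis_limit(self, rng):
        x = rng.standard_normal(100_000)
        assert channel_stats(x)["kurt"] == pytest.approx(3.0, abs=0.1)


finite_windows = arrays(
    float, st.integers(8, 64),
    elements=st.floats(-1e3, 1e3, allow_nan=False, width=32),
).filter(lambda x: np.std(x) > 1e-6)


class TestProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x=finite_windows, c=st.floats(0.1, 100.0))
    def test_scale_equivariance(self, x, c):
        f1, f2 = compute_time_features(x), compute_time_features(c * x)
        for name in ("mu", "sigma", "delta", "gamma_diff", "mav", "med",
                     "rms", "rss", "maxmin"):
            assert getattr(f2, name) == pytest.approx(c * getattr(f1, name),
                                                      rel=1e-6, abs=1e-9)
        for name in ("delta_norm", "gamma_norm", "prms", "kurt"):
            assert getattr(f2, name) == pytest.approx(getattr(f1, name),
                                                      rel=1e-6, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x=finite_windows, c=st.floats(-100.0, 100.0))
    def test_shift_invariance(self, x, c):
        f1, f2 = compute_time_features(x), compute_time_features(x + c)
        for name in ("sigma", "delta", "gamma_diff", "maxmin", "kurt"):
            assert getattr(f2, name) == pytest.approx(getattr(f1, name),
                                                      rel=1e-5, abs=1e-8)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x=finite_windows)
    def test_rss_rms_identity(self, x):
        f = compute_time_features(x)
        assert f.rss == pytest.approx(f.rms * np.sqrt(len(x)), rel=1e-9)
        assert f.prms >= 1.0 - 1e-12
        assert f.pk >= f.med >= f.min_amp


class TestDegenerateInputs:
    def test_zero_variance_sentinels_not_exceptions(self):
        with pytest.warns(UserWarning):
            _, _, dn, gn = difference_stats([2.0] * 10)
        assert np.isnan(dn) and np.isnan(gn)
        with pytest.warns(UserWarning):
            stats = epoch_statistics(np.full((8, 1), 3.0))["CH0"]
        assert np.isnan(stats.skewness) and np.isnan(stats.kurtosis)

    def test_too_short_windows_raise(self):
        with pytest.raises(ValueError):
            raw_moments([1.0])
        with pytest.raises(ValueError):
            difference_stats([1.0, 2.0])
        with pytest.raises(ValueError):
            channel_stats([1.0, 2.0])
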