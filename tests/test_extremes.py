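import numpy as np
import pandas as pd
import pytest

from strokecast.extremes import (
    binarize_fixed_first_n, binarize_past_percentile, build_ext,
    default_nknots, detrend_spline, rolling_mean, rolling_sum,
)


def series(values, start="2015-01-01"):
    idx = pd.date_range(start, periods=len(values))
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestRolling:
    def test_constant_input(self):
        out = rolling_sum(series([1] * 10), window=7)
        assert out.iloc[:6].isna().all()
        assert (out.iloc[6:] == 7).all()

    def test_hand_summation(self):
        out = rolling_sum(series(range(1, 9)), window=7)
        assert out.iloc[6] == 28 and out.iloc[7] == 35
        m = rolling_mean(series(range(1, 9)), window=7)
        assert m.iloc[6] == 4.0 and m.iloc[7] == 5.0

    def test_missing_day_propagates(self):
        vals = [1.0] * 20
        vals[9] = np.nan
        out = rolling_sum(series(vals), window=7)
        assert out.iloc[9:16].isna().all()
        assert out.iloc[8] == 7 and out.iloc[16] == 7

    def test_window_one_is_identity(self):
        s = series([3, 1, 4, 1, 5])
        pd.testing.assert_series_equal(rolling_mean(s, window=1), s)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            rolling_sum(series([1, 2, 3]), window=0)


class TestDetrendSpline:
    def test_reproduces_linear_trend(self):
        n = 1000
        s = series(2.0 + 0.5 * np.arange(n))
        out = detrend_spline(s)
        rng_ = s.max() - s.min()
        assert out["residual"].abs().max() < 1e-6 * rng_

    def test_constant_series(self):
        out = detrend_spline(series([5.0] * 200))
        assert out["residual"].abs().max() < 1e-5

    def test_noise_sd_recovered_around_seasonal_signal(self, rng):
        n = 2000
        t = np.arange(n)
        y = 10 * np.sin(2 * np.pi * t / 365) + rng.normal(0, 1, n)
        out = detrend_spline(series(y))
        assert 0.85 <= out["residual"].std() <= 1.15

    def test_identity_decomposition(self, rng):
        y = rng.normal(0, 1, 500).cumsum()
        out = detrend_spline(series(y))
        np.testing.assert_allclose(out["trend"] + out["residual"], out["value"],
                                   rtol=0, atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="10"):
            detrend_spline(series([1.0] * 9))

    def test_missing_values_stay_missing(self, rng):
        y = rng.normal(size=300)
        y[50:60] = np.nan
        out = detrend_spline(series(y))
        assert out["trend"][50:60].isna().all()
        assert out["residual"].notna().sum() == 290

    def test_knot_rule_monotone(self):
        ns = [60, 200, 800, 1826, 3200]
        ks = [default_nknots(n) for n in ns]
        assert ks == sorted(ks) and all(k < n for k, n in zip(ks[1:], ns[1:]))


def naive_past_percentile(values, q, min_history):
    """O(n²) oracle: re-sort the full past on every day."""
    n = len(values)
    ext = np.full(n, np.nan)
    cut = np.full(n, np.nan)
    for t in range(n):
        past = values[:t]
        past = past[~np.isnan(past)]
        if len(past) < min_history or np.isnan(values[t]):
            continue
        c = np.quantile(past, q)
        cut[t] = c
        ext[t] = float(values[t] > c)
    return ext, cut


class TestBinarizePastPercentile:
    def test_strictly_increasing_all_extreme(self):
        out = binarize_past_percentile(series(np.arange(300.0)), min_history=50)
        assert (out["ext"].dropna() == 1).all()
        assert out["ext"].isna().sum() == 50

    def test_constant_never_extreme(self):
        out = binarize_past_percentile(series([4.0] * 300), min_history=50)
        assert (out["ext"].dropna() == 0).all()

    def test_iid_rate_near_design_level(self, rng):
        vals = rng.standard_normal(2000)
        out = binarize_past_percentile(series(vals), q=0.90, min_history=100)
        rate = out["ext"].mean()
        assert 0.08 <= rate <= 0.12

    def test_matches_naive_oracle_exactly(self, rng):
        vals = rng.standard_normal(800)
        vals[100:105] = np.nan
        s = series(vals)
        out = binarize_past_percentile(s, q=0.9, min_history=60)
        ext_o, cut_o = naive_past_percentile(vals, 0.9, 60)
        np.testing.assert_array_equal(out["ext"].to_numpy(), ext_o)
        np.testing.assert_allclose(out["cutoff"].to_numpy(), cut_o, equal_nan=True)

    @pytest.mark.parametrize("q", [0.0, 1.0, 1.5])
    def test_invalid_quantile(self, q):
        with pytest.raises(ValueError):
            binarize_past_percentile(series(np.arange(200.0)), q=q)


class TestBinarizeFixedFirstN:
    def test_step_change_detected(self):
        vals = [0.0] * 500 + [1.0] * 100
        out = binarize_fixed_first_n(series(vals), n_init=500)
        assert (out["ext"].iloc[500:] == 1).all()
        assert out["ext"].iloc[:500].isna().all()

    def test_constant_series(self):
        out = binarize_fixed_first_n(series([2.0] * 600), n_init=500)
        assert (out["ext"].dropna() == 0).all()

    def test_iid_uniform_rate(self, rng):
        out = binarize_fixed_first_n(series(rng.uniform(size=5000)), n_init=500)
        assert 0.08 <= out["ext"].mean() <= 0.12

    def test_too_short(self):
        with pytest.raises(ValueError):
            binarize_fixed_first_n(series([1.0] * 400), n_init=500)


class TestBuildExt:
    def test_all_zero_counts_never_extreme(self):
        counts = series([0.0] * 400)
        out = build_ext(counts, min_history=100)
        assert (out["ext"].dropna() == 0).all()

    def test_upto_too_small(self, small_dataset):
        counts, _ = small_dataset
        with pytest.raises(ValueError):
            build_ext(counts, upto=50)

    def test_truncation_stability(self, small_dataset):
        """Re-running the construction on a longer history perturbs only a
        modest fraction of the binary classifications: the GCV penalty,
        the knot count and the running thresholds all shift a little, so
        days whose residual sits close to the 90th-percentile cutoff can
        flip. Measured instability on this data is ~11% of days; the test
        bounds it at 15%."""
        counts, _ = small_dataset
        a = build_ext(counts, upto=500)["ext"]
        b = build_ext(counts, upto=865)["ext"]
        both = a.notna() & b.notna().reindex(a.index, fill_value=False)
        disagree = (a[both] != b.reindex(a.index)[both]).mean()
        assert disagree < 0.15

    def test_exchangeable_rate_calibration(self, rng):
        """For exchangeable residual input the post-warm-up extreme rate
        sits at 1 - q within ±2 percentage points (n=2000)."""
        vals = rng.standard_normal(2000)
        out = binarize_past_percentile(series(vals), q=0.90, min_history=100)
        assert abs(out["ext"].mean() - 0.10) <= 0.02

    def test_fixed_mode_dispatch(self, small_dataset):
        counts, _ = small_dataset
        out = build_ext(counts, mode="fixed", n_init=500)
        assert out["cutoff"].dropna().nunique() == 1

    def test_attrs_carry_penalty(self, small_dataset):
        counts, _ = small_dataset
        out = build_ext(counts)
        assert out.attrs["lam"] > 0 and out.attrs["edf"] > 4
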