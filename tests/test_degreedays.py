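import numpy as np
import pandas as pd
import pytest
from scipy import stats

from budworm import degreedays
from budworm.degreedays import accumulate, calibrate, dd_at_collection, single_triangulation


def triangle_area_oracle(tmin, tmax, t_lower, t_upper=None):
    """Independent oracle: clip each linear segment of the diurnal triangle
    against the threshold and integrate exactly."""

    def segment_area(t0, v0, t1, v1, level):
        if v0 <= level and v1 <= level:
            return 0.0
        if v0 >= level and v1 >= level:
            return ((v0 - level) + (v1 - level)) / 2.0 * (t1 - t0)
        tc = t0 + (level - v0) / (v1 - v0) * (t1 - t0)
        if v0 < level:  # rising across the threshold
            return (v1 - level) / 2.0 * (t1 - tc)
        return (v0 - level) / 2.0 * (tc - t0)

    def area(level):
        return segment_area(0.0, tmin, 0.5, tmax, level) + segment_area(
            0.5, tmax, 1.0, tmin, level
        )

    out = area(t_lower)
    if t_upper is not None:
        out -= area(t_upper)
    return out


class TestSingleTriangulation:
    @pytest.mark.parametrize(
        "tmin,tmax,expect",
        [(10, 20, 9.5), (-5, 4, 0.0), (0, 11, 1.375)],
    )
    def test_reference_days(self, tmin, tmax, expect):
        assert single_triangulation(tmin, tmax) == pytest.approx(expect)

    def test_regime_boundary_continuity(self):
        # tmin exactly at the threshold: both branches give (tmax - T_L)/2
        t_l = 5.5
        assert single_triangulation(t_l, 15.5, t_l) == pytest.approx(5.0)
        assert single_triangulation(t_l + 1e-9, 15.5, t_l) == pytest.approx(5.0, abs=1e-8)

    def test_matches_integration_oracle_randomized(self):
        rng = np.random.default_rng(0)
        tmin = rng.uniform(-15, 20, 500)
        tmax = tmin + rng.uniform(0, 20, 500)
        t_l = rng.uniform(-5, 15, 500)
        got = np.array(
            [single_triangulation(a, b, c) for a, b, c in zip(tmin, tmax, t_l)]
        )
        want = np.array(
            [triangle_area_oracle(a, b, c) for a, b, c in zip(tmin, tmax, t_l)]
        )
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_upper_threshold_subtracts_apex(self):
        got = single_triangulation(10, 45, 5.5, t_upper=38.0)
        want = triangle_area_oracle(10, 45, 5.5, t_upper=38.0)
        assert got == pytest.approx(want, abs=1e-9)

    def test_inverted_day_rejected(self):
        with pytest.raises(ValueError):
            single_triangulation(10, 5)


def _series(location, dates, tmin, tmax, source="station"):
    return pd.DataFrame(
        {
            "location": location,
            "date": pd.to_datetime(dates),
            "tmin_c": tmin,
            "tmax_c": tmax,
            "source": source,
        }
    )


class TestCalibrate:
    def test_constant_offset_recovered_exactly(self):
        dates = pd.date_range("2018-06-01", periods=30)
        station = _series("d", dates, 5.0, 15.0)
        logger = _series("d", dates, 6.5, 16.5, source="logger")
        res, corrected = calibrate(logger, station)
        assert res.median_diff_tmin == pytest.approx(1.5)
        assert res.median_diff_tmax == pytest.approx(1.5)
        np.testing.assert_allclose(corrected["tmin_c"], 6.5)

    def test_identity_yields_zero_correction(self):
        dates = pd.date_range("2018-06-01", periods=10)
        station = _series("d", dates, np.linspace(0, 9, 10), np.linspace(10, 19, 10))
        res, corrected = calibrate(station.copy(), station)
        assert res.median_diff_tmin == 0.0
        np.testing.assert_allclose(corrected["tmax_c"], station["tmax_c"])

    def test_median_of_mixed_diffs(self):
        dates = pd.date_range("2018-06-01", periods=3)
        station = _series("d", dates, [0.0, 0.0, 0.0], [10.0, 10.0, 10.0])
        logger = _series("d", dates, [1.0, 2.0, -0.5], [11.0, 12.0, 9.5])
        res, _ = calibrate(logger, station)
        assert res.median_diff_tmin == pytest.approx(1.0)

    def test_no_overlap_rejected(self):
        a = _series("d", pd.date_range("2018-06-01", periods=3), 0.0, 10.0)
        b = _series("d", pd.date_range("2018-07-01", periods=3), 0.0, 10.0)
        with pytest.raises(ValueError):
            calibrate(a, b)

    def test_zero_offset_statistically_null_over_seeds(self):
        """With no true offset the paired rank test is null (p ~ uniform);
        the unpaired variant on the same paired series never rejects."""
        pvals, pvals_unpaired = [], []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            dates = pd.date_range("2018-06-01", periods=60)
            base = 10 + 5 * rng.standard_normal(60)
            station = _series("d", dates, base - 5, base + 5)
            noise = 0.5 * rng.standard_normal(60)
            logger = _series("d", dates, base - 5 + noise, base + 5 + noise)
            res, _ = calibrate(logger, station, paired_test=True)
            pvals.append(res.pvalue)
            res_u, _ = calibrate(logger, station)
            pvals_unpaired.append(res_u.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert min(pvals_unpaired) > 0.05

    def test_signed_rank_variant(self):
        dates = pd.date_range("2018-06-01", periods=20)
        rng = np.random.default_rng(1)
        base = 10 + rng.standard_normal(20)
        station = _series("d", dates, base - 5, base + 5)
        logger = _series("d", dates, base - 5 + 2.0, base + 5 + 2.0)
        res, _ = calibrate(logger, station, paired_test=True)
        assert res.test == "wilcoxon_signed_rank"
        assert res.pvalue < 0.01


class TestAccumulate:
    def test_all_below_threshold(self):
        t = _series("d", pd.date_range("2018-01-01", periods=20), -10.0, 2.0)
        out = accumulate(t)
        assert (out["cum_dd"] == 0).all()

    def test_constant_days(self):
        t = _series("d", pd.date_range("2018-06-01", periods=10), 10.0, 20.0)
        out = accumulate(t)
        assert out["cum_dd"].iloc[-1] == pytest.approx(95.0)

    def test_cumsum_matches_daily_definition(self):
        rng = np.random.default_rng(2)
        tmin = rng.uniform(-5, 15, 50)
        t = _series("d", pd.date_range("2018-05-01", periods=50), tmin, tmin + 8)
        out = accumulate(t)
        np.testing.assert_allclose(
            out["cum_dd"].to_numpy(), np.cumsum(out["dd"].to_numpy()), atol=1e-12
        )
        np.testing.assert_allclose(
            out["dd"].to_numpy(), single_triangulation(tmin, tmin + 8), atol=1e-12
        )

    def test_restart_each_january(self):
        dates = list(pd.date_range("2017-12-29", periods=6))
        t = _series("d", dates, 10.0, 20.0)
        out = accumulate(t)
        jan1 = out[out["date"] == "2018-01-01"]["cum_dd"].iloc[0]
        assert jan1 == pytest.approx(9.5)

    def test_gap_interpolated_and_counted(self):
        dates = pd.to_datetime(["2018-06-01", "2018-06-02", "2018-06-04"])
        t = _series("d", dates, [10.0, 10.0, 14.0], [20.0, 20.0, 24.0])
        out = accumulate(t)
        assert len(out) == 4
        gap = out[out["date"] == "2018-06-03"]
        assert bool(gap["interpolated"].iloc[0])
        assert gap["tmin_c"].iloc[0] if "tmin_c" in gap else True
        assert gap["dd"].iloc[0] == pytest.approx((12 + 22) / 2 - 5.5)


class TestDdAtCollection:
    def _table(self):
        t = _series("d", pd.date_range("2018-06-01", periods=10), 10.0, 20.0)
        return accumulate(t)

    def test_inclusive_end_day(self):
        samples = pd.DataFrame(
            {"location": ["d"], "collection_date": [pd.Timestamp("2018-06-03")]}
        )
        out = dd_at_collection(self._table(), samples)
        assert out.iloc[0] == pytest.approx(3 * 9.5)

    def test_date_before_series_rejected(self):
        samples = pd.DataFrame(
            {"location": ["d"], "collection_date": [pd.Timestamp("2018-05-01")]}
        )
        with pytest.raises(ValueError, match="2018-05-01"):
            dd_at_collection(self._table(), samples)

    def test_same_location_date_identical(self):
        samples = pd.DataFrame(
            {
                "location": ["d", "d"],
                "collection_date": [pd.Timestamp("2018-06-05")] * 2,
            }
        )
        out = dd_at_collection(self._table(), samples)
        assert out.iloc[0] == out.iloc[1]
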