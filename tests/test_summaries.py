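"""Aggregation, intervals, significance, masking, disparity summaries."""

import numpy as np
import pytest
import xarray as xr

from countyhale.strata import DRAW_DIM
from countyhale.summaries import (
    aggregate_weighted,
    compare,
    county_disparity_stats,
    mask_small,
    null_comparison_rate,
    pairwise_significant_counts,
    percent,
    point_and_ui,
    round_half_up,
)


def sc(x):
    """Scalar from a size-1 array-like."""
    return float(np.asarray(x).ravel()[0])


def _cube(values, dims=("county", DRAW_DIM), **coords):
    values = np.asarray(values, dtype=float)
    coords = coords or {
        "county": [f"c{i}" for i in range(values.shape[0])],
        DRAW_DIM: np.arange(values.shape[-1]),
    }
    return xr.DataArray(values, dims=dims, coords=coords)


class TestAggregateWeighted:
    def test_equal_weights_simple_mean(self):
        cube = _cube([[64.0] * 4, [68.0] * 4])
        w = xr.DataArray([1.0, 1.0], dims=("county",),
                         coords={"county": ["c0", "c1"]})
        out = aggregate_weighted(cube, w, "county")
        np.testing.assert_allclose(out.values, 66.0)

    def test_singleton_group_identity(self):
        cube = _cube([[1.0, 2.0, 3.0]])
        w = xr.DataArray([5.0], dims=("county",), coords={"county": ["c0"]})
        out = aggregate_weighted(cube, w, "county")
        np.testing.assert_allclose(out.values, [1.0, 2.0, 3.0])

    def test_summary_of_aggregate_not_aggregate_of_summaries(self):
        # the UI of the aggregate must come from aggregated draws, which
        # is narrower than averaging the stratum-level UIs when draws are
        # imperfectly correlated
        rng = np.random.default_rng(3)
        cube = _cube(rng.normal(70, 3, size=(6, 400)))
        w = xr.DataArray(np.ones(6), dims=("county",),
                         coords={"county": [f"c{i}" for i in range(6)]})
        agg = aggregate_weighted(cube, w, "county")
        ui_of_agg = point_and_ui(agg)
        agg_of_ui = point_and_ui(cube)["upper"].mean()
        width = float(ui_of_agg["upper"] - ui_of_agg["lower"])
        naive_width = float(
            (point_and_ui(cube)["upper"] - point_and_ui(cube)["lower"]).mean()
        )
        assert width < naive_width
        assert float(ui_of_agg["mean"]) == pytest.approx(
            float(cube.mean()), rel=1e-12
        )

    def test_zero_weights_rejected(self):
        cube = _cube([[1.0, 2.0], [3.0, 4.0]])
        w = xr.DataArray([0.0, 0.0], dims=("county",),
                         coords={"county": ["c0", "c1"]})
        with pytest.raises(ValueError):
            aggregate_weighted(cube, w, "county")


class TestPointAndUi:
    def test_constant_draws(self):
        out = point_and_ui(_cube([[7.0] * 10]))
        assert sc(out["mean"]) == 7.0
        assert sc(out["lower"]) == 7.0
        assert sc(out["upper"]) == 7.0

    def test_linear_interpolation_quantiles(self):
        # draws 1..1000: the 2.5th/97.5th percentiles under linear
        # interpolation between order statistics
        out = point_and_ui(_cube([np.arange(1.0, 1001.0)]))
        assert sc(out["lower"]) == pytest.approx(25.975)
        assert sc(out["upper"]) == pytest.approx(975.025)

    def test_mean_invariant_to_permutation(self, rng):
        vals = rng.normal(size=(1, 200))
        a = point_and_ui(_cube(vals))
        b = point_and_ui(_cube(vals[:, ::-1].copy()))
        assert sc(a["mean"]) == pytest.approx(sc(b["mean"]))

    def test_nan_draw_rejected(self):
        vals = np.ones((1, 10))
        vals[0, 3] = np.nan
        with pytest.raises(ValueError):
            point_and_ui(_cube(vals))

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            point_and_ui(_cube([[1.0]]))


class TestCompare:
    def _pair(self, n_pos, n=1000):
        a = np.zeros((1, n))
        a[0, :n_pos] = 1.0
        b = np.zeros((1, n))
        return _cube(a), _cube(b)

    def test_rule_boundary_significant(self):
        a, b = self._pair(980)
        res = compare(a, b)
        assert sc(res.posterior_prob) == pytest.approx(0.98)
        assert bool(res.significant.values.ravel()[0])

    def test_rule_boundary_not_significant(self):
        a, b = self._pair(970)
        res = compare(a, b)
        assert sc(res.posterior_prob) == pytest.approx(0.97)
        assert not bool(res.significant.values.ravel()[0])

    def test_ties_count_as_not_greater(self):
        a = _cube([[1.0] * 1000])
        res = compare(a, a)
        assert sc(res.posterior_prob) == 0.0
        # identical cubes: all differences are exactly zero; conservative
        # tie handling means prob 0, which the rule flags as significant
        # on the low side -- but a zero mean difference is reported
        assert sc(res.difference) == 0.0

    def test_unaligned_draws_rejected(self):
        with pytest.raises(ValueError):
            compare(_cube(np.ones((1, 10))), _cube(np.ones((1, 12))))

    def test_significance_despite_overlapping_intervals(self, rng):
        # correlated draws: the paired difference is decisive even though
        # the marginal 95% intervals overlap substantially
        base = rng.normal(0, 1, 1000)
        a = _cube([base + 0.1])
        b = _cube([base])
        res = compare(a, b)
        assert bool(res.significant.values.ravel()[0])
        ui_a = point_and_ui(a)
        ui_b = point_and_ui(b)
        assert sc(ui_a["lower"]) < sc(ui_b["upper"])


class TestMasking:
    def _pop(self, county_race_totals, n_years=3):
        vals = np.asarray(county_race_totals, dtype=float)
        n_c, n_r = vals.shape
        arr = np.zeros((n_c, n_r, 2, 2, n_years))
        # split each county-race total over 2 sexes and 2 age groups,
        # constant over years
        arr[:] = vals[:, :, None, None, None] / 4.0
        return xr.DataArray(
            arr,
            dims=("county", "race", "sex", "age", "year"),
            coords={
                "county": [f"c{i}" for i in range(n_c)],
                "race": ["black", "white"][:n_r],
                "sex": ["female", "male"],
                "age": ["0-45", "45+"],
                "year": list(range(2009, 2009 + n_years)),
            },
        )

    def test_boundary_999_masked_1000_not(self):
        pop = self._pop([[999.0], [1000.0]])
        out = mask_small(pop, threshold=1000)
        assert bool(out["masked"].values[0, 0])
        assert not bool(out["masked"].values[1, 0])
        np.testing.assert_allclose(
            out["mean_annual_population"].values.ravel(), [999.0, 1000.0]
        )

    def test_zero_threshold_masks_nothing(self):
        pop = self._pop([[5.0], [999.0]])
        out = mask_small(pop, threshold=0)
        assert not out["masked"].values.any()

    def test_missing_population_rejected(self):
        pop = self._pop([[100.0], [200.0]])
        pop.values[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            mask_small(pop)


class TestDisparityStats:
    def test_range_from_reported_extremes(self):
        # county HALE spanning 50.1 to 74.6 years is a 24.5-year range
        vals = xr.DataArray(
            np.array([50.1, 60.0, 62.5, 74.6]), dims=("county",),
            coords={"county": list("abcd")},
        )
        out = county_disparity_stats(vals)
        assert out["range"] == pytest.approx(24.5)
        assert out["min"] == 50.1 and out["max"] == 74.6

    def test_single_county(self):
        vals = xr.DataArray([63.0], dims=("county",), coords={"county": ["a"]})
        out = county_disparity_stats(vals)
        assert out["range"] == 0.0
        assert out["median"] == 63.0

    def test_masked_counties_excluded(self):
        vals = xr.DataArray(
            np.array([50.0, 60.0, 70.0]), dims=("county",),
            coords={"county": list("abc")},
        )
        masked = xr.DataArray(
            np.array([True, False, False]), dims=("county",),
            coords={"county": list("abc")},
        )
        out = county_disparity_stats(vals, masked=masked)
        assert out["n_counties"] == 2
        assert out["min"] == 60.0

    def test_change_percentages_match_reported_rounding(self):
        # 2 812 declining counties of 3 079 is 91.3%
        n = 3079
        sig = np.zeros(n, dtype=bool)
        sig[:2812] = True
        sign = np.where(sig, -1.0, 1.0)
        vals = xr.DataArray(
            np.full(n, 64.0), dims=("county",),
            coords={"county": [f"c{i}" for i in range(n)]},
        )
        out = county_disparity_stats(
            vals,
            change_significant=xr.DataArray(
                sig, dims=("county",), coords={"county": vals["county"].values}
            ),
            change_sign=xr.DataArray(
                sign, dims=("county",), coords={"county": vals["county"].values}
            ),
        )
        assert out["n_significant_decline"] == 2812
        assert out["pct_significant_decline"] == 91.3

    def test_empty_after_masking_rejected(self):
        vals = xr.DataArray([60.0], dims=("county",), coords={"county": ["a"]})
        masked = xr.DataArray([True], dims=("county",), coords={"county": ["a"]})
        with pytest.raises(ValueError):
            county_disparity_stats(vals, masked=masked)


class TestRounding:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (2812, 3079, 91.3),
            (2019, 3079, 65.6),
            (58, 3079, 1.9),
            (96, 666, 14.4),
            (558, 1478, 37.8),
            (2008, 3051, 65.8),
            (412, 1487, 27.7),
            (276, 472, 58.5),
            (44, 658, 6.7),
            (51, 1469, 3.5),
            (139, 1485, 9.4),
            (82, 327, 25.1),
        ],
    )
    def test_reported_county_percentages(self, count, total, expected):
        assert percent(count, total) == expected

    def test_half_up(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(-0.05, 1) == -0.1


class TestCalibration:
    def test_null_significance_rate_near_nominal(self):
        rate = null_comparison_rate(
            n_replicates=1000, n_draws=1000, seed=123
        )
        assert 0.03 <= rate <= 0.07


class TestPairwiseCounts:
    def test_counts_and_denominators(self, rng):
        n = 40
        counties = [f"c{i}" for i in range(n)]
        a = _cube(rng.normal(70, 0.05, (n, 200)),
                  county=counties, draw=np.arange(200))
        b = _cube(rng.normal(69.5, 0.05, (n, 200)),
                  county=counties, draw=np.arange(200))
        res = compare(a, b)
        masks = {
            "x": xr.DataArray(np.zeros(n, bool), dims=("county",),
                              coords={"county": counties}),
            "y": xr.DataArray(
                np.arange(n) < 10, dims=("county",),
                coords={"county": counties},
            ),
        }
        df = pairwise_significant_counts({("x", "y"): res}, masks)
        row = df.iloc[0]
        assert row["n_counties"] == 30
        assert row["a_higher"] <= 30
        assert row["pct_a_higher"] == percent(row["a_higher"], 30)
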