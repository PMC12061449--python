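import numpy as np
import pandas as pd
import pytest

from treeline_drivers.change import (
    CoverSeries,
    annual_rate,
    change_map,
    density_increase,
    sector_summary,
    slope_distribution,
)
from treeline_drivers.raster import RasterGrid

from conftest import make_grid


def series_from_arrays(years, arrays, cell=50.0):
    return CoverSeries(
        years, {y: RasterGrid(np.asarray(a, float), cell_size=cell) for y, a in zip(years, arrays)}
    )


class TestChangeMap:
    def test_identical_maps_have_no_change(self):
        m = np.eye(4)
        cm = change_map(series_from_arrays([2000, 2010], [m, m]), 2000, 2010)
        assert cm.counts["expanded"] == 0
        assert cm.counts["reduced"] == 0
        assert cm.counts["present-stable"] == 4

    def test_single_added_cell(self):
        m1 = np.zeros((3, 3))
        m2 = m1.copy()
        m2[1, 1] = 1
        cm = change_map(series_from_arrays([1, 2], [m1, m2]), 1, 2)
        assert cm.counts["expanded"] == 1
        assert cm.categories.values[1, 1] == 2

    def test_random_pair_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(13)
        m1 = (rng.random((20, 20)) < 0.4).astype(float)
        m2 = (rng.random((20, 20)) < 0.5).astype(float)
        cm = change_map(series_from_arrays([1, 2], [m1, m2]), 1, 2)
        brute = {"absent-stable": 0, "present-stable": 0, "expanded": 0, "reduced": 0}
        for r in range(20):
            for c in range(20):
                key = {(0, 0): "absent-stable", (1, 1): "present-stable",
                       (0, 1): "expanded", (1, 0): "reduced"}[(m1[r, c], m2[r, c])]
                brute[key] += 1
        assert cm.counts == brute

    def test_missing_year_rejected(self):
        s = series_from_arrays([1, 2], [np.zeros((3, 3))] * 2)
        with pytest.raises(ValueError):
            change_map(s, 1, 3)

    def test_nested_series_is_expansion_only(self, small_scene):
        series = small_scene["series"]
        years = series.years
        for y1, y2 in zip(years[:-1], years[1:]):
            cm = change_map(series, y1, y2)
            assert cm.counts["reduced"] == 0
            assert series.area_hm2(y2) >= series.area_hm2(y1)


class TestAnnualRate:
    def test_no_change_is_zero(self):
        assert annual_rate(100.0, 100.0, 5.0) == 0.0

    def test_paper_convention_total_rate(self):
        # 24.26% total increase over a 20-year span
        assert annual_rate(100.0, 124.26, 20.0) == pytest.approx(1.213)
        assert round(annual_rate(100.0, 124.26, 20.0), 2) == 1.21

    def test_doubling_over_ten_years(self):
        assert annual_rate(50.0, 100.0, 10.0) == pytest.approx(10.0)

    def test_zero_base_area_rejected(self):
        with pytest.raises(ValueError):
            annual_rate(0.0, 10.0, 5.0)


class TestSectorSummary:
    @staticmethod
    def scene(presence_by_year, dem_values):
        years = sorted(presence_by_year)
        series = series_from_arrays(years, [presence_by_year[y] for y in years], cell=10.0)
        dem = RasterGrid(np.asarray(dem_values, float), cell_size=10.0)
        return series, dem

    def test_max_elevation_of_single_presence_cell(self):
        pres = np.zeros((9, 9))
        pres[0, 4] = 1  # due north of centre
        dem = np.full((9, 9), 1000.0)
        dem[0, 4] = 2100.0
        series, dem_grid = self.scene({2002: pres, 2021: pres}, dem)
        sectors = RasterGrid(np.ones((9, 9)), cell_size=10.0)  # all "northern"
        out = sector_summary(series, sectors, dem_grid, sector_names={1: "northern"})
        elev = out["max_elevation"]
        north = elev[(elev["sector"] == "northern") & (elev["year"] == 2002)]
        assert north["max_elevation_m"].iloc[0] == 2100.0

    def test_unchanged_presence_has_zero_rates(self):
        pres = np.zeros((6, 6))
        pres[3:, :] = 1
        series, dem_grid = self.scene({2000: pres, 2010: pres}, np.ones((6, 6)))
        sectors = RasterGrid(np.ones((6, 6)), cell_size=10.0)
        out = sector_summary(series, sectors, dem_grid)
        assert np.allclose(out["rates"]["annual_rate_pct"], 0.0)

    def test_scripted_growth_matches_bookkeeping(self):
        # sector 1 grows 2 -> 4 cells over 10 years; sector 2 stays at 3 cells
        sectors = np.ones((6, 6))
        sectors[:, 3:] = 2
        p1 = np.zeros((6, 6))
        p1[0, 0] = p1[0, 1] = 1           # sector 1: 2 cells
        p1[0, 3] = p1[0, 4] = p1[0, 5] = 1  # sector 2: 3 cells
        p2 = p1.copy()
        p2[1, 0] = p2[1, 1] = 1           # sector 1 doubles
        series, dem_grid = self.scene({2000: p1, 2010: p2}, np.ones((6, 6)))
        out = sector_summary(series, RasterGrid(sectors, cell_size=10.0), dem_grid,
                             sector_names={1: "west", 2: "east"})
        rates = out["rates"].set_index(["sector", "period"])["annual_rate_pct"]
        assert rates[("west", "2000-2010")] == pytest.approx(10.0)  # doubling / 10 a
        assert rates[("east", "2000-2010")] == 0.0
        # explicit span override (stated-span convention)
        out20 = sector_summary(series, RasterGrid(sectors, cell_size=10.0), dem_grid,
                               sector_names={1: "west", 2: "east"},
                               spans={(2000, 2010): 20.0})
        rates20 = out20["rates"].set_index(["sector", "period"])["annual_rate_pct"]
        assert rates20[("west", "2000-2010")] == pytest.approx(5.0)

    def test_sector_areas_sum_to_total(self, small_scene):
        from treeline_drivers.terrain import assign_aspect_sector

        dem = small_scene["dem"]
        summit = (dem.ncols * dem.cell_size / 2, -dem.nrows * dem.cell_size / 2)
        sectors = assign_aspect_sector(dem, summit)
        series = small_scene["series"]
        out = sector_summary(series, sectors, dem)
        areas = out["areas"]
        for y in series.years:
            by_year = areas[areas["year"] == y].set_index("sector")["area_hm2"]
            sector_sum = by_year.drop("total").sum()
            assert sector_sum == pytest.approx(by_year["total"])


class TestSlopeDistribution:
    def test_all_presence_in_one_class(self):
        pres = np.ones((4, 4))
        series = series_from_arrays([2020], [pres])
        slope_cls = make_grid(np.full((4, 4), 3.0), cell_size=50.0)
        table = slope_distribution(series, slope_cls)
        assert table.loc[table["slope_class"] == 3, "percent"].iloc[0] == 100.0

    def test_even_split_between_two_classes(self):
        pres = np.ones((4, 4))
        cls = np.full((4, 4), 2.0)
        cls[:2, :] = 5.0
        series = series_from_arrays([2020], [pres])
        table = slope_distribution(series, make_grid(cls, cell_size=50.0))
        by_class = table.set_index("slope_class")["percent"]
        assert by_class[2] == by_class[5] == 50.0

    def test_random_map_matches_exhaustive_tally_and_sums_to_100(self):
        rng = np.random.default_rng(21)
        pres = (rng.random((12, 12)) < 0.5).astype(float)
        cls = rng.integers(1, 8, (12, 12)).astype(float)
        series = series_from_arrays([2021], [pres])
        table = slope_distribution(series, make_grid(cls, cell_size=50.0))
        total_pres = pres.sum()
        for k in range(1, 8):
            expected = 100.0 * np.sum((pres == 1) & (cls == k)) / total_pres
            assert table.set_index("slope_class")["percent"][k] == pytest.approx(expected)
        assert table["percent"].sum() == pytest.approx(100.0)


class TestDensityIncrease:
    @staticmethod
    def change_of(m1, m2):
        return change_map(series_from_arrays([1, 2], [m1, m2]), 1, 2)

    def test_fully_expanded_block_is_100(self):
        cm = self.change_of(np.zeros((10, 10)), np.ones((10, 10)))
        assert np.all(density_increase(cm, 10).values == 100.0)

    def test_no_expansion_is_zero(self):
        m = np.eye(10)
        cm = self.change_of(m, m)
        assert np.all(density_increase(cm, 10).values == 0.0)

    def test_partial_block_fraction(self):
        m1 = np.zeros((10, 10))
        m2 = np.zeros((10, 10))
        m2.ravel()[:37] = 1  # 37 of 100 cells expand
        cm = self.change_of(m1, m2)
        assert density_increase(cm, 10).values[0, 0] == pytest.approx(37.0)

    def test_aggregation_one_reproduces_indicator(self):
        rng = np.random.default_rng(2)
        m1 = (rng.random((8, 8)) < 0.3).astype(float)
        m2 = np.maximum(m1, (rng.random((8, 8)) < 0.3).astype(float))
        cm = self.change_of(m1, m2)
        dens = density_increase(cm, 1).values
        np.testing.assert_allclose(dens, 100.0 * (cm.categories.values == 2))

    def test_values_bounded(self, small_scene):
        series = small_scene["series"]
        cm = change_map(series, series.years[0], series.years[-1])
        dens = density_increase(cm, 10).values
        finite = dens[np.isfinite(dens)]
        assert finite.min() >= 0.0 and finite.max() <= 100.0

    def test_bad_aggregation_rejected(self):
        cm = self.change_of(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            density_increase(cm, 0)
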