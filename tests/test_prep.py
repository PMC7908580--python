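import datetime as dt

import numpy as np
import pandas as pd
import pytest

import maupmtup as m


class TestGridToAreas:
    def test_constant_field_maps_to_constant(self, small_lattice):
        f = m.RainfallField(
            dates=pd.date_range("2001-01-01", periods=3, freq="D"),
            cell_ids=list(small_lattice.cell_ids),
            values=np.full((3, len(small_lattice.cell_ids)), 2.5),
        )
        unit_daily = m.map_grid_to_areas(f, small_lattice)
        assert np.allclose(unit_daily, 2.5)

    def test_weighted_mean(self):
        lat = m.gen_lattice(2, 2, 1, (10, 10), seed=0)
        from scipy import sparse
        lat.overlap_weights = sparse.csr_matrix(
            np.array([[0.25, 0.75, 0, 0]] + [[0, 0, 0, 1.0]] * 3)
        )
        f = m.RainfallField(
            dates=pd.date_range("2001-01-01", periods=1, freq="D"),
            cell_ids=list(lat.cell_ids),
            values=np.array([[0.0, 4.0, 1.0, 1.0]]),
        )
        assert m.map_grid_to_areas(f, lat)[0, 0] == pytest.approx(3.0)

    def test_convex_combination_bound(self, small_lattice, rng):
        """Unit values always lie within [min, max] of that day's cell values."""
        n_cells = len(small_lattice.cell_ids)
        values = rng.uniform(0, 10, size=(1000, n_cells))
        f = m.RainfallField(
            dates=pd.date_range("2000-01-01", periods=1000, freq="D"),
            cell_ids=list(small_lattice.cell_ids),
            values=values,
        )
        unit_daily = m.map_grid_to_areas(f, small_lattice)
        lo = values.min(axis=1, keepdims=True) - 1e-9
        hi = values.max(axis=1, keepdims=True) + 1e-9
        assert ((unit_daily >= lo) & (unit_daily <= hi)).all()

    def test_unknown_cell_rejected_naming_unit(self, small_lattice):
        f = m.RainfallField(
            dates=pd.date_range("2001-01-01", periods=1, freq="D"),
            cell_ids=["bogus"],
            values=np.zeros((1, 1)),
        )
        with pytest.raises(ValueError, match="unit 0"):
            m.map_grid_to_areas(f, small_lattice)


class TestInterpolatePopulation:
    CD = (dt.date(2006, 1, 1), dt.date(2011, 1, 1))

    def test_linear_midpoint(self):
        pops = np.array([[100.0, 200.0]])
        window = (dt.date(2008, 1, 1), dt.date(2008, 12, 31))  # midpoint ~2008-07-01
        got = m.interpolate_population(self.CD, pops, window)
        assert got[0] == pytest.approx(150.0, abs=1.0)

    def test_census_date_returns_census_value(self):
        pops = np.array([[100.0, 200.0]])
        window = (dt.date(2010, 7, 2), dt.date(2011, 7, 1))  # midpoint 2011-01-01
        assert m.interpolate_population(self.CD, pops, window)[0] == pytest.approx(200.0, abs=0.5)

    def test_extrapolation_floored_at_zero(self):
        # 100 -> 40 over 5 years (-12/yr) extrapolates to -20 at 2016; floored
        pops = np.array([[100.0, 40.0]])
        window = (dt.date(2015, 7, 2), dt.date(2016, 7, 1))
        raw = 40.0 - 12.0 * 5.0  # hand-computed line at 2016
        assert raw < 0
        assert m.interpolate_population(self.CD, pops, window)[0] == 0.0

    def test_fewer_than_two_censuses_rejected(self):
        with pytest.raises(ValueError, match="two census"):
            m.interpolate_population((dt.date(2006, 1, 1),), np.array([[5.0]]),
                                     (dt.date(2006, 1, 1), dt.date(2006, 12, 31)))


@pytest.fixture(scope="module")
def setup():
    lat = m.gen_lattice(1, 4, 1, (100, 100), seed=0)
    windows = m.window_instances(
        dt.date(2010, 1, 1), dt.date(2011, 12, 31), m.WindowArrangement(12, 3, 0)
    )
    dates = pd.date_range("2009-01-01", "2012-01-31", freq="D")
    return lat, windows, dates


class TestAggregation:
    def test_events_and_population_additive(self, setup):
        lat, windows, dates = setup
        events = np.array([[3], [4], [0], [1]]) * np.ones((4, len(windows)), dtype=int)
        pops = np.full((4, len(windows)), 100.0)
        daily = np.ones((len(dates), 4))
        z = m.Zonation(labels=np.array([0, 0, 1, 1]), target_pop=200)
        ds = m.aggregate_by_zonation(z, events, pops, daily, dates, windows)
        zone0 = ds.data[ds.data["zone"] == 0]
        assert (zone0["y"] == 7).all()
        assert (zone0["pop"] == 200.0).all()

    def test_zone_rainfall_is_unweighted_unit_mean(self, setup):
        lat, windows, dates = setup
        daily = np.column_stack([
            np.full(len(dates), 1.0), np.full(len(dates), 2.0),
            np.full(len(dates), 5.0), np.full(len(dates), 5.0),
        ])
        events = np.ones((4, len(windows)), dtype=int)
        pops = np.full((4, len(windows)), 10.0)
        z = m.Zonation(labels=np.array([0, 0, 1, 1]), target_pop=0)
        ds = m.aggregate_by_zonation(z, events, pops, daily, dates, windows)
        assert np.allclose(ds.data[ds.data["zone"] == 0]["x"], 1.5)
        assert np.allclose(ds.data[ds.data["zone"] == 1]["x"], 5.0)

    def test_conservation_under_random_zonation(self, small_lattice, rng):
        windows = m.window_instances(
            dt.date(2010, 1, 1), dt.date(2013, 12, 31), m.WindowArrangement(12, 6, 6)
        )
        n, w = small_lattice.n_units, len(windows)
        events = rng.poisson(4.0, (n, w))
        pops = rng.uniform(50, 150, (n, w))
        dates = pd.date_range("2008-06-01", "2014-01-31", freq="D")
        daily = rng.uniform(0, 3, (len(dates), n))
        z = m.build_zonation(small_lattice, 900, seed=2)
        ds = m.aggregate_by_zonation(z, events, pops, daily, dates, windows)
        for j, win in enumerate(windows):
            sub = ds.data[ds.data["window_id"] == win.window_id]
            assert sub["y"].sum() == events[:, j].sum()
            assert sub["pop"].sum() == pytest.approx(pops[:, j].sum())

    def test_row_count_is_zones_times_windows(self, small_lattice, rng):
        windows = m.window_instances(
            dt.date(2002, 1, 1), dt.date(2017, 6, 30), m.WindowArrangement(12, 3, 0)
        )
        assert len(windows) == 15
        n = small_lattice.n_units
        events = rng.poisson(2.0, (n, 15))
        pops = np.full((n, 15), 80.0)
        dates = pd.date_range("1999-08-01", "2017-06-30", freq="D")
        daily = rng.uniform(0, 3, (len(dates), n))
        z = m.build_zonation(small_lattice, 1500, seed=3)
        ds = m.aggregate_by_zonation(z, events, pops, daily, dates, windows)
        assert len(ds.data) == z.n_zones * 15

    def test_incomplete_assignment_rejected(self, setup):
        lat, windows, dates = setup
        z = m.Zonation(labels=np.array([0, 0, 1, -1]), target_pop=0)
        with pytest.raises(ValueError, match="assign"):
            m.aggregate_by_zonation(
                z, np.ones((4, len(windows)), dtype=int),
                np.ones((4, len(windows))), np.ones((len(dates), 4)), dates, windows,
            )
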