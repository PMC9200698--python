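"""DEM conditioning, D-infinity routing, delineation and the exposure table."""

import sys

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from shortcutflux.connectivity import (
    ConnectivityParams,
    build_exposure_table,
    condition_dem,
    delineate_contributing_areas,
    flow_accumulation,
    flow_directions_dinf,
    monte_carlo_connectivity,
)
from shortcutflux.geometry import Plot, Site


def _east_tilt(n=8, m=10, scale=1.0):
    return np.tile(np.arange(m, 0, -1.0), (n, 1)) * scale


class TestConditioning:
    def test_plane_without_roads_unchanged(self):
        dem = _east_tilt(20, 20)
        out = condition_dem(dem, ConnectivityParams())
        assert np.allclose(out, dem)

    def test_shallow_pit_filled(self):
        dem = _east_tilt(20, 20, scale=0.01)
        dem[10, 10] -= 0.05  # 0.04 m below its pour level
        out = condition_dem(dem, ConnectivityParams(sink_fill_depth=0.1))
        assert out[10, 10] > dem[10, 10] + 0.03

    def test_deep_pit_retained_as_sink(self):
        dem = _east_tilt(20, 20, scale=0.01)
        dem[10, 10] -= 0.5
        out = condition_dem(dem, ConnectivityParams(sink_fill_depth=0.1))
        assert out[10, 10] == dem[10, 10]

    def test_road_cells_carved(self):
        dem = _east_tilt(20, 20)
        roads = np.zeros_like(dem, dtype=bool)
        roads[5, :] = True
        out = condition_dem(dem, ConnectivityParams(road_carving_depth=0.2), roads)
        assert np.allclose(out[5, 2:-2], dem[5, 2:-2] - 0.2)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            condition_dem(_east_tilt(20, 20), ConnectivityParams(), np.zeros((5, 5), bool))

    def test_undefined_cells_rejected(self):
        dem = _east_tilt(20, 20)
        dem[3, 3] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            condition_dem(dem, ConnectivityParams())


def _oracle_accumulation(fd, n):
    """Exhaustive fractional path routing: push each cell's unit area
    down every branching flow path (independent of the production code's
    topological-order accumulation)."""
    sys.setrecursionlimit(100_000)
    acc = np.zeros(n)

    def push(i, mass):
        acc[i] += mass
        for k in range(2):
            j = fd.receivers[i, k]
            if j >= 0:
                push(j, mass * fd.weights[i, k])

    for i in range(n):
        push(i, 1.0)
    return acc


class TestDinf:
    def test_uniform_east_tilt_sends_all_flow_east(self):
        dem = _east_tilt()
        fd = flow_directions_dinf(dem, 1.0)
        n, m = dem.shape
        for r in range(n):
            for c in range(m - 1):
                i = r * m + c
                assert fd.receivers[i, 0] == i + 1
                assert fd.weights[i, 0] == pytest.approx(1.0)
                assert fd.weights[i, 1] == 0.0

    def test_diagonal_direction_splits_fifty_fifty(self):
        # slope direction exactly between east and north-east
        n, m = 12, 12
        ang = np.pi / 8
        x = np.arange(m)[None, :]
        y = (n - 1 - np.arange(n))[:, None] * 1.0
        dem = 100.0 - (np.cos(ang) * x + np.sin(ang) * y)
        fd = flow_directions_dinf(dem, 1.0)
        i = (n // 2) * m + m // 2
        w = fd.weights[i]
        assert w[0] == pytest.approx(0.5, abs=1e-9)
        assert w[1] == pytest.approx(0.5, abs=1e-9)

    def test_accumulation_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            dem = rng.random((6, 6)) * 2 + np.arange(6)[::-1][:, None] * 0.5
            fd = flow_directions_dinf(dem, 1.0)
            acc = flow_accumulation(dem, fd, 1.0).ravel()
            oracle = _oracle_accumulation(fd, dem.size)
            assert np.allclose(acc, oracle, rtol=1e-9)


class TestDelineation:
    def test_bowl_drains_entirely_to_inlet(self):
        rr, cc = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
        bowl = ((rr - 10) ** 2 + (cc - 10) ** 2) * 0.01
        fd = flow_directions_dinf(bowl, 1.0)
        inlet = np.zeros_like(bowl, bool)
        inlet[10, 10] = True
        ca = delineate_contributing_areas(bowl, fd, [("I001", inlet)], 1.0)
        assert ca.area["I001"] == bowl.size

    def test_plane_to_stream_edge_all_stream(self):
        dem = np.arange(20, 0, -1.0)[:, None] * np.ones((1, 15))  # drains south
        stream = np.zeros_like(dem, bool)
        stream[-1, :] = True
        fd = flow_directions_dinf(dem, 1.0)
        ca = delineate_contributing_areas(dem, fd, [("stream", stream)], 1.0)
        assert ca.area["stream"] == dem.size

    def test_partition_sums_to_catchment_area(self, small_catchment):
        cat = small_catchment
        params = ConnectivityParams()
        cond = condition_dem(cat.dem, params, cat.road_mask)
        fd = flow_directions_dinf(cond, cat.cell_size)
        ca = delineate_contributing_areas(cond, fd, cat.destinations(), cat.cell_size)
        total = cat.dem.size * cat.cell_size**2
        assert sum(ca.area.values()) == pytest.approx(total)
        assert sum(ca.frac_area.values()) == pytest.approx(total, rel=1e-9)

    def test_carving_monotonicity(self, small_catchment):
        """More road carving never decreases road area draining to inlets."""
        cat = small_catchment
        inlet_road_area = []
        for depth in (0.0, 0.1, 0.3):
            params = ConnectivityParams(road_carving_depth=depth, sink_fill_depth=0.1)
            cond = condition_dem(cat.dem, params, cat.road_mask)
            fd = flow_directions_dinf(cond, cat.cell_size)
            ca = delineate_contributing_areas(
                cond, fd, cat.destinations(), cat.cell_size, road_mask=cat.road_mask
            )
            inlet_road_area.append(
                sum(v for k, v in ca.road_area.items() if k.startswith("I"))
            )
        assert inlet_road_area[0] <= inlet_road_area[1] <= inlet_road_area[2]


class TestMonteCarlo:
    def test_point_mass_distributions_give_identical_runs(self, small_catchment):
        cat = small_catchment
        params = ConnectivityParams(
            road_carving_range=(0.15, 0.15), sink_fill_range=(0.1, 0.1)
        )
        runs, _ = monte_carlo_connectivity(
            cat.dem, params, cat.destinations(), roads_mask=cat.road_mask,
            agri_mask=cat.agri_mask, n_runs=4, seed=0, cell_size=cat.cell_size,
        )
        assert runs["frac_via_inlet"].nunique() == 1

    def test_median_within_run_range(self, small_catchment):
        cat = small_catchment
        runs, summary = monte_carlo_connectivity(
            cat.dem, ConnectivityParams(), cat.destinations(), roads_mask=cat.road_mask,
            agri_mask=cat.agri_mask, n_runs=8, seed=1, cell_size=cat.cell_size,
        )
        med = summary.loc["frac_via_inlet", "median"]
        assert runs["frac_via_inlet"].min() <= med <= runs["frac_via_inlet"].max()

    def test_invalid_run_count_rejected(self, small_catchment):
        with pytest.raises(ValueError):
            monte_carlo_connectivity(
                small_catchment.dem, ConnectivityParams(), small_catchment.destinations(),
                n_runs=0, seed=0,
            )


class _FakeApp:
    def __init__(self, app_id, substance, date, plot_id, mass_g):
        self.application_id = app_id
        self.substance = substance
        self.date = pd.Timestamp(date)
        self.plot_id = plot_id
        self.mass_g = mass_g


class TestExposureTable:
    def _setup(self):
        """A south-draining plane with one inlet; a plot inside its CA and
        plots at controlled distances outside it."""
        n, m = 40, 120
        dem = np.arange(n, 0, -1.0)[:, None] * np.ones((1, m)) * 0.1
        inlet_mask = np.zeros((n, m), bool)
        inlet_mask[-1, 5] = True
        stream = np.zeros((n, m), bool)
        stream[-1, :] = True
        stream[-1, 5] = False
        fd = flow_directions_dinf(dem, 1.0)
        ca = delineate_contributing_areas(dem, fd, [("I001", inlet_mask), ("stream", stream)], 1.0)
        site = Site("I1", Point(5.5, 0.5), ("I001",))
        return ca, site

    def test_plot_inside_ca_has_runoff_potential(self):
        ca, site = self._setup()
        plots = [Plot("P1", box(4.6, 10, 6.4, 20))]  # directly upslope of the inlet
        apps = [_FakeApp(1, "metamitron", "2019-05-01", "P1", 100.0)]
        table, rejected = build_exposure_table(ca, plots, apps, None, [site])
        assert rejected == []
        row = table.iloc[0]
        assert row["runoff"] and row["mass_in_ca_g"] > 0

    def test_far_plot_without_link_is_absent(self):
        ca, site = self._setup()
        plots = [Plot("P1", box(110, 30, 118, 38))]  # ~110 m away, other CA
        apps = [_FakeApp(1, "metamitron", "2019-05-01", "P1", 100.0)]
        table, _ = build_exposure_table(ca, plots, apps, None, [site])
        assert len(table) == 0

    @pytest.mark.parametrize("gap_m,expected", [(99.0, True), (101.0, False)])
    def test_drift_boundary_at_100m(self, gap_m, expected):
        ca, site = self._setup()
        # plot edge exactly gap_m east of the site point, outside the CA column
        plots = [Plot("P1", box(5.5 + gap_m, 0.0, 5.5 + gap_m + 5, 5.0))]
        apps = [_FakeApp(1, "metamitron", "2019-05-01", "P1", 100.0)]
        table, _ = build_exposure_table(ca, plots, apps, None, [site])
        if expected:
            assert len(table) == 1 and bool(table.iloc[0]["drift_direct"])
        else:
            assert len(table) == 0

    def test_unknown_plot_rejected_with_report(self):
        ca, site = self._setup()
        apps = [_FakeApp(1, "metamitron", "2019-05-01", "NOPE", 100.0)]
        table, rejected = build_exposure_table(ca, [], apps, None, [site])
        assert len(table) == 0 and len(rejected) == 1
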