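import math

import numpy as np
import pytest
from shapely.geometry import box

from windcross.kinematics import AirspeedPolicy, great_circle
from windcross.route_graph import (
    GridConstructionError,
    Node,
    UnresolvableArrivalError,
    arrival_node_for_dead_bird,
    build_grid,
    match_wind_time,
    minimal_flight_time,
    restrict_informed,
    snap_to_lattice,
)
from windcross.wind_model import STANDARD_LEVELS_MB, WindField, analysis_times, sample_wind

from conftest import make_constant_field
from oracles import exhaustive_minimal_route

POLICY = AirspeedPolicy()


class TestBuildGrid:
    def test_node_count_includes_boundaries(self):
        grid = build_grid(box(0, 0, 2, 2), levels=STANDARD_LEVELS_MB)
        assert grid.n_nodes == 6 * 6 * 16

    def test_interior_degree(self):
        grid = build_grid(box(0, 0, 2, 2), levels=(925, 850, 750))
        centre = Node(1.2, 1.2, 850.0)
        assert len(grid.successors(centre)) == 8 * 3

    def test_top_layer_has_no_up_moves(self):
        grid = build_grid(box(0, 0, 2, 2), levels=STANDARD_LEVELS_MB)
        top = Node(1.2, 1.2, 500.0)
        assert {n.level for n in grid.successors(top)} == {500.0, 550.0}

    def test_bottom_layer_has_no_down_moves(self):
        grid = build_grid(box(0, 0, 2, 2), levels=STANDARD_LEVELS_MB)
        bottom = Node(1.2, 1.2, 1000.0)
        assert {n.level for n in grid.successors(bottom)} == {1000.0, 975.0}

    def test_no_purely_vertical_moves(self):
        grid = build_grid(box(0, 0, 2, 2), levels=(925, 850))
        node = Node(1.2, 1.2, 925.0)
        assert all(
            (s.lat, s.lon) != (node.lat, node.lon) for s in grid.successors(node)
        )

    def test_required_point_outside_corridor(self):
        with pytest.raises(GridConstructionError):
            build_grid(box(0, 0, 2, 2), require=[(5.0, 5.0)])

    def test_snap_to_lattice(self):
        assert snap_to_lattice(10.01, -6.19) == (10.0, -6.0)
        assert snap_to_lattice(10.21, -6.21) == (10.4, -6.4)


class TestRestrictInformed:
    def test_informed_subset_of_uninformed(self):
        grid = build_grid(box(0, 0, 2, 2), levels=(925, 850))
        informed = restrict_informed(grid, [(0.2, 0.2), (1.0, 1.0), (1.8, 1.8)], buffer=0.5)
        assert informed.nodes <= grid.nodes
        assert informed.variant == "informed"

    def test_huge_buffer_recovers_full_grid(self):
        grid = build_grid(box(0, 0, 2, 2), levels=(925, 850))
        informed = restrict_informed(grid, [(1.0, 1.0)], buffer=1e6)
        assert informed.nodes == grid.nodes

    def test_small_buffer_narrow_corridor(self):
        grid = build_grid(box(0, 0, 2, 2), levels=(925,))
        # fixes straight up the lon=0.8 lattice line
        informed = restrict_informed(grid, [(0.0, 0.8), (2.0, 0.8)], buffer=0.2)
        lons = {n.lon for n in informed.nodes}
        assert lons == {0.8}  # one cell wide: only the track's own column

    def test_all_levels_retained(self):
        grid = build_grid(box(0, 0, 2, 2), levels=(925, 850, 750))
        informed = restrict_informed(grid, [(1.0, 1.0)], buffer=0.5)
        assert {n.level for n in informed.nodes} == {925.0, 850.0, 750.0}

    def test_endpoints_always_kept(self):
        grid = build_grid(box(0, 0, 2, 2), levels=(925,))
        informed = restrict_informed(
            grid, [(1.0, 1.0)], buffer=0.2, departure=(0.0, 0.0), arrival=(2.0, 2.0)
        )
        assert Node(0.0, 0.0, 925.0) in informed.nodes
        assert Node(2.0, 2.0, 925.0) in informed.nodes

    def test_needs_at_least_one_fix(self):
        grid = build_grid(box(0, 0, 2, 2), levels=(925,))
        with pytest.raises(ValueError):
            restrict_informed(grid, [], buffer=0.5)


class TestMatchWindTime:
    def test_departure_node_matches_departure_time(self):
        node = Node(0.0, 0.0, 925.0)
        t = match_wind_time(node, node, "2016-04-01T07:10")
        assert t == np.datetime64("2016-04-01T06:00:00")

    def test_straight_line_offset(self):
        # 650.7 km at 18.05 m/s is 10.013 h: departing 00:00, the nearest
        # analysis to the 10:01 estimate is 12:00
        dep = Node(0.0, 0.0, 925.0)
        # find a latitude offset ~650.7 km north
        dist_per_deg, _ = great_circle((0.0, 0.0), (1.0, 0.0))
        dlat = 650_700.0 / dist_per_deg
        node = Node(round(dlat, 6), 0.0, 925.0)
        t = match_wind_time(node, dep, "2016-04-01T00:00")
        assert t == np.datetime64("2016-04-01T12:00:00")

    def test_equidistant_nodes_same_time(self):
        dep = Node(0.0, 0.0, 925.0)
        east = Node(0.0, 0.8, 925.0)
        west = Node(0.0, -0.8, 925.0)
        t0 = "2016-04-01T00:00"
        assert match_wind_time(east, dep, t0) == match_wind_time(west, dep, t0)

    def test_midpoint_tie_goes_earlier(self):
        node = Node(0.0, 0.0, 925.0)
        t = match_wind_time(node, node, "2016-04-01T03:00")
        assert t == np.datetime64("2016-04-01T00:00:00")


def chain_grid_and_field(u=0.0, v=0.0, n_cols=6):
    """A single-row west-to-east corridor on the equator, one level."""
    lon1 = 0.4 * (n_cols - 1)
    corridor = box(-0.1, -0.1, lon1 + 0.1, 0.1)
    grid = build_grid(corridor, levels=(925,))
    field = make_constant_field(u, v, lat0=-0.4, lat1=0.4, lon0=-0.4,
                                lon1=lon1 + 0.4, levels=(925,))
    return grid, field


class TestMinimalFlightTime:
    def test_zero_wind_equals_distance_over_airspeed(self):
        grid, field = chain_grid_and_field(0.0, 0.0)
        dep, arr = Node(0.0, 0.0, 925.0), Node(0.0, 2.0, 925.0)
        res = minimal_flight_time(grid, field, dep, arr, "2016-04-01T00:00")
        leg, _ = great_circle((0.0, 0.0), (0.0, 0.4))
        expected_h = 5 * leg / 18.05 / 3600.0
        assert res.reachable
        assert res.total_time_h == pytest.approx(expected_h, rel=1e-9)
        assert res.path[0] == dep and res.path[-1] == arr

    @pytest.mark.parametrize("w", [2.0, 5.0, 10.0])
    def test_uniform_tailwind_scales_time(self, w):
        grid0, field0 = chain_grid_and_field(0.0, 0.0)
        gridw, fieldw = chain_grid_and_field(w, 0.0)
        dep, arr = Node(0.0, 0.0, 925.0), Node(0.0, 2.0, 925.0)
        t0 = minimal_flight_time(grid0, field0, dep, arr, "2016-04-01T00:00").total_time_h
        tw = minimal_flight_time(gridw, fieldw, dep, arr, "2016-04-01T00:00").total_time_h
        assert tw == pytest.approx(t0 * 18.05 / (18.05 + w), rel=1e-9)

    def test_total_time_is_sum_of_edges(self):
        grid, field = chain_grid_and_field(3.0, 1.0)
        dep, arr = Node(0.0, 0.0, 925.0), Node(0.0, 2.0, 925.0)
        res = minimal_flight_time(grid, field, dep, arr, "2016-04-01T00:00")
        assert res.total_time_h == pytest.approx(sum(res.per_edge_times_s) / 3600.0)

    def test_overwhelming_headwind_unreachable(self):
        grid, field = chain_grid_and_field(-18.05, 0.0)
        dep, arr = Node(0.0, 0.0, 925.0), Node(0.0, 2.0, 925.0)
        res = minimal_flight_time(grid, field, dep, arr, "2016-04-01T00:00")
        assert not res.reachable
        assert math.isinf(res.total_time_h)
        assert res.path == ()

    def test_tailwind_never_increases_time(self):
        # uniform improvement along the travel direction
        dep, arr = Node(0.0, 0.0, 925.0), Node(0.0, 2.0, 925.0)
        times = []
        for w in [0.0, 1.0, 3.0, 6.0, 10.0]:
            grid, field = chain_grid_and_field(w, 0.0)
            times.append(
                minimal_flight_time(grid, field, dep, arr, "2016-04-01T00:00").total_time_h
            )
        assert all(t2 <= t1 for t1, t2 in zip(times, times[1:]))

    def test_departure_missing_from_grid(self):
        grid, field = chain_grid_and_field()
        with pytest.raises(GridConstructionError):
            minimal_flight_time(
                grid, field, Node(5.0, 5.0, 925.0), Node(0.0, 2.0, 925.0),
                "2016-04-01T00:00",
            )


def random_wind_grid(seed, n=4, levels=(925.0, 850.0), max_speed=6.0):
    """A small corridor with random per-cell winds for oracle comparison."""
    rng = np.random.default_rng(seed)
    lon1 = lat1 = 0.4 * (n - 1)
    corridor = box(0, 0, lon1, lat1)
    grid = build_grid(corridor, levels=levels)
    times = analysis_times("2016-04-01T00:00", 2)
    lats = np.round(np.arange(-0.4, lat1 + 0.6, 0.4), 6)
    lons = np.round(np.arange(-0.4, lon1 + 0.6, 0.4), 6)
    shape = (len(times), len(levels), len(lats), len(lons))
    u = rng.uniform(-max_speed, max_speed, size=shape)
    v = rng.uniform(-max_speed, max_speed, size=shape)
    u[1:] = u[0]  # static in time: both analyses identical
    v[1:] = v[0]
    field = WindField(
        times=times, levels=np.asarray(sorted(levels, reverse=True), float),
        lats=lats, lons=lons, u=u, v=v,
    )
    return grid, field, max_speed * math.sqrt(2)


class TestDijkstraAgainstExhaustiveSearch:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_grid_agreement(self, seed):
        grid, field, max_wind = random_wind_grid(seed)
        dep = Node(0.0, 0.0, 925.0)
        arr = Node(1.2, 1.2, 850.0)
        t0 = "2016-04-01T00:00"
        res = minimal_flight_time(grid, field, dep, arr, t0)

        def wind_at(node):
            return sample_wind(field, node.lat, node.lon, node.level, t0)

        best_t, best_hops, best_path = exhaustive_minimal_route(
            grid, wind_at, dep, arr, POLICY, max_wind=max_wind
        )
        assert res.total_time_h * 3600.0 == pytest.approx(best_t, rel=1e-12)
        assert len(res.path) - 1 == best_hops
        assert res.path == best_path

    def test_zero_wind_tie_break_agreement(self):
        # abundant exact ties: the tie-break (fewer edges, then
        # lexicographic node order) must match the oracle's
        grid, field, _ = random_wind_grid(0)
        field.u[:] = 0.0
        field.v[:] = 0.0
        dep = Node(0.0, 0.0, 925.0)
        arr = Node(1.2, 1.2, 925.0)
        t0 = "2016-04-01T00:00"
        res = minimal_flight_time(grid, field, dep, arr, t0)
        best_t, best_hops, best_path = exhaustive_minimal_route(
            grid, lambda n: (0.0, 0.0), dep, arr, POLICY, max_wind=0.0
        )
        assert res.total_time_h * 3600.0 == best_t
        assert res.path == best_path


class TestAgainstNetworkxDijkstra:
    """Cross-check of the optimal cost against an independent
    shortest-path library on the same weighted graph."""

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_total_time_matches_networkx(self, seed):
        import networkx as nx

        from windcross.route_graph import match_wind_time

        grid, field, _ = random_wind_grid(seed, n=4)
        dep = Node(0.0, 0.0, 925.0)
        arr = Node(1.2, 1.2, 850.0)
        t0 = "2016-04-01T00:00"
        res = minimal_flight_time(grid, field, dep, arr, t0)

        g = nx.DiGraph()
        for node in grid.nodes:
            t = match_wind_time(node, dep, t0)
            w = sample_wind(field, node.lat, node.lon, node.level, t)
            for nxt in grid.successors(node):
                from windcross.kinematics import edge_travel_time

                dt = edge_travel_time((node.lat, node.lon), (nxt.lat, nxt.lon), w, POLICY)
                if math.isfinite(dt):
                    g.add_edge(node, nxt, weight=dt)
        ref = nx.dijkstra_path_length(g, dep, arr)
        assert res.total_time_h * 3600.0 == pytest.approx(ref, rel=1e-12)


class TestArrivalNodeForDeadBird:
    class _C:
        def __init__(self, season, departure_time, arrival_node):
            self.season = season
            self.departure_time = departure_time
            self.arrival_node = arrival_node

    def test_single_prior(self):
        a = Node(2.0, 0.0, 925.0)
        hist = [self._C("northward", "2015-04-10", a)]
        assert arrival_node_for_dead_bird(hist) == a

    def test_most_recent_prior_wins(self):
        a, b = Node(2.0, 0.0, 925.0), Node(2.4, 0.0, 925.0)
        hist = [
            self._C("northward", "2015-04-10", a),
            self._C("northward", "2016-04-12", b),
        ]
        assert arrival_node_for_dead_bird(hist) == b

    def test_no_prior_unresolvable(self):
        hist = [self._C("southward", "2015-10-10", Node(0.0, 0.0, 925.0))]
        with pytest.raises(UnresolvableArrivalError):
            arrival_node_for_dead_bird(hist)
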