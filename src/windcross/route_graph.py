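"""The 3D route graph and minimal-flight-time search.

Candidate flight positions form a lattice of nodes (lat, lon on a 0.4
degree grid by default; altitude as a pressure level) restricted to a
migration-corridor polygon.  Moves connect a node to its 8 horizontal
lattice neighbours at the same level or one level up/down; purely
vertical moves are rejected because a zero-length edge would have zero
cost and make altitude changes free.  Edge weights are travel times under
the wind sampled at the origin node, matched to the nearest 6-hourly
analysis of the node's straight-line arrival-time estimate.  Because the
matched time depends only on the crossing's origin, edge weights are
static for a given departure and plain Dijkstra is exact.

Two grid variants exist: the *uninformed* grid is the full corridor; the
*informed* grid keeps only nodes near the piecewise-linear interpolation
of an individual's retrieved in-flight locations.  The informed node set
is a subset of the uninformed one, so the uninformed minimal time is, by
definition, equal to or shorter than the informed one.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .kinematics import INFEASIBLE, AirspeedPolicy, edge_travel_time, great_circle
from .wind_model import WindField, as_utc64, sample_wind

logger = logging.getLogger(__name__)

_COORD_DECIMALS = 6  # lattice coordinates are rounded so equality is exact


class Node(NamedTuple):
    """A candidate flight position: lattice lat/lon (deg) and level (mb)."""

    lat: float
    lon: float
    level: float


class GridConstructionError(ValueError):
    """The corridor polygon cannot support the requested grid."""


class UnresolvableArrivalError(LookupError):
    """No prior completed northward crossing supplies an arrival node."""


@dataclass(frozen=True)
class NodeGrid:
    """A set of lattice nodes with implicit adjacency.

    ``variant`` is "uninformed" (full corridor) or "informed" (restricted
    to a buffer around observed in-flight locations).
    """

    nodes: frozenset[Node]
    levels: tuple[float, ...]  # strictly decreasing, mb
    resolution: float
    variant: str
    corridor: Polygon

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def successors(self, node: Node) -> list[Node]:
        """Lattice neighbours: 8 horizontal moves x {same, up, down} level."""
        res = self.resolution
        idx = self.levels.index(node.level)
        level_choices = [node.level]
        if idx > 0:
            level_choices.append(self.levels[idx - 1])   # higher pressure = down
        if idx < len(self.levels) - 1:
            level_choices.append(self.levels[idx + 1])   # lower pressure = up
        out = []
        for dlat in (-res, 0.0, res):
            for dlon in (-res, 0.0, res):
                if dlat == 0.0 and dlon == 0.0:
                    continue  # no purely vertical moves
                lat = round(node.lat + dlat, _COORD_DECIMALS)
                lon = round(node.lon + dlon, _COORD_DECIMALS)
                for lev in level_choices:
                    cand = Node(lat, lon, lev)
                    if cand in self.nodes:
                        out.append(cand)
        return out


@dataclass(frozen=True)
class RouteResult:
    """Outcome of a minimal-flight-time search."""

    total_time_h: float
    path: tuple[Node, ...]
    per_edge_times_s: tuple[float, ...]
    variant: str
    departure_time: np.datetime64

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.total_time_h)


def snap_to_lattice(lat: float, lon: float, resolution: float = 0.4) -> tuple[float, float]:
    """Round a point to the nearest lattice intersection."""
    return (
        round(round(lat / resolution) * resolution, _COORD_DECIMALS),
        round(round(lon / resolution) * resolution, _COORD_DECIMALS),
    )


def build_grid(
    corridor: Polygon,
    resolution: float = 0.4,
    levels: Sequence[float] = (925.0, 850.0, 750.0, 650.0),
    require: Iterable[tuple[float, float]] = (),
) -> NodeGrid:
    """Build the uninformed grid: all lattice nodes inside the corridor.

    Lattice lines sit at integer multiples of ``resolution``; polygon
    boundaries are inclusive.  ``require`` lists (lat, lon) points (e.g.
    departure and arrival) whose lattice cells must be present; a corridor
    excluding one raises :class:`GridConstructionError`.
    """
    levels = tuple(sorted((float(x) for x in levels), reverse=True))
    minx, miny, maxx, maxy = corridor.bounds  # shapely: x=lon, y=lat
    eps = 1e-9
    lon_lines = np.round(
        np.arange(math.floor(minx / resolution) * resolution, maxx + resolution / 2, resolution),
        _COORD_DECIMALS,
    )
    lat_lines = np.round(
        np.arange(math.floor(miny / resolution) * resolution, maxy + resolution / 2, resolution),
        _COORD_DECIMALS,
    )
    poly = corridor.buffer(eps)  # boundary-inclusive
    lon_mesh, lat_mesh = np.meshgrid(lon_lines, lat_lines)
    inside = shapely.covers(poly, shapely.points(lon_mesh.ravel(), lat_mesh.ravel()))
    horiz = {
        (float(lat), float(lon))
        for lat, lon, ok in zip(lat_mesh.ravel(), lon_mesh.ravel(), inside)
        if ok
    }
    nodes = frozenset(Node(lat, lon, lev) for (lat, lon) in horiz for lev in levels)
    for lat, lon in require:
        cell = snap_to_lattice(lat, lon, resolution)
        if cell not in horiz:
            raise GridConstructionError(
                f"required point ({lat}, {lon}) snaps to {cell}, outside the corridor"
            )
    return NodeGrid(
        nodes=nodes, levels=levels, resolution=resolution,
        variant="uninformed", corridor=corridor,
    )


def restrict_informed(
    grid: NodeGrid,
    fixes: Sequence[tuple[float, float]],
    buffer: float = 0.5,
    departure: tuple[float, float] | None = None,
    arrival: tuple[float, float] | None = None,
) -> NodeGrid:
    """Restrict a grid to a corridor around observed in-flight locations.

    Keeps nodes within ``buffer`` degrees of the piecewise-linear
    interpolation of the ordered (lat, lon) fixes (distance measured in
    planar degree space; at 0.4 degree scale the difference from the
    central angle is far below one cell).  All levels are retained — Argos
    fixes carry no altitude.  Departure/arrival cells, when given, are
    always kept so the route endpoints survive the restriction.
    """
    if len(fixes) < 1:
        raise ValueError("informed restriction needs at least one in-flight fix")
    waypoints = list(fixes)
    if departure is not None:
        waypoints.insert(0, departure)
    if arrival is not None:
        waypoints.append(arrival)
    if len(waypoints) == 1:
        track = Point(waypoints[0][1], waypoints[0][0])
    else:
        track = LineString([(lon, lat) for lat, lon in waypoints])
    keep_cells = set()
    for node in grid.nodes:
        cell = (node.lat, node.lon)
        if cell in keep_cells:
            continue
        if track.distance(Point(node.lon, node.lat)) <= buffer + 1e-12:
            keep_cells.add(cell)
    for pt in (departure, arrival):
        if pt is not None:
            keep_cells.add(snap_to_lattice(pt[0], pt[1], grid.resolution))
    nodes = frozenset(n for n in grid.nodes if (n.lat, n.lon) in keep_cells)
    return NodeGrid(
        nodes=nodes, levels=grid.levels, resolution=grid.resolution,
        variant="informed", corridor=grid.corridor,
    )


def match_wind_time(
    node: Node,
    departure_node: Node,
    departure_time,
    policy: AirspeedPolicy = AirspeedPolicy(),
) -> np.datetime64:
    """Nearest 6-hourly analysis to the straight-line arrival estimate.

    estimate = departure_time + great_circle(departure, node) / airspeed,
    rounded to the nearest 0:00/6:00/12:00/18:00 UTC analysis (ties toward
    the earlier analysis).  Static per departure, which is what keeps the
    edge weights fixed and plain Dijkstra exact.
    """
    t0 = as_utc64(departure_time)
    dist, _ = great_circle((departure_node.lat, departure_node.lon), (node.lat, node.lon))
    est = t0 + np.timedelta64(int(round(dist / policy.airspeed)), "s")
    day = est.astype("datetime64[D]").astype("datetime64[s]")
    secs = float((est - day) / np.timedelta64(1, "s"))
    k = secs / 21600.0
    lower = math.floor(k)
    # round to nearest 6-h slot; an exact midpoint goes to the earlier one
    slot = lower if (k - lower) <= 0.5 else lower + 1
    return day + np.timedelta64(int(slot * 21600), "s")


def _node_winds(
    grid: NodeGrid,
    field: WindField,
    departure: Node,
    departure_time,
    policy: AirspeedPolicy,
) -> Callable[[Node], tuple[float, float]]:
    cache: dict[Node, tuple[float, float]] = {}

    def wind_at(node: Node) -> tuple[float, float]:
        w = cache.get(node)
        if w is None:
            t = match_wind_time(node, departure, departure_time, policy)
            w = sample_wind(field, node.lat, node.lon, node.level, t)
            cache[node] = w
        return w

    return wind_at


def minimal_flight_time(
    grid: NodeGrid,
    field: WindField,
    departure: Node,
    arrival: Node,
    departure_time,
    policy: AirspeedPolicy = AirspeedPolicy(),
) -> RouteResult:
    """Minimum-travel-time route from departure to arrival node.

    Dijkstra on the lattice with labels ordered lexicographically by
    (total time, edge count, node sequence), which yields a deterministic,
    bit-stable optimal path: ties in time are broken by fewer edges, then
    by lexicographic node order.  An exhausted search returns an explicit
    unreachable result with infinite time.
    """
    if departure not in grid.nodes:
        raise GridConstructionError(f"departure node {departure} not in grid")
    if arrival not in grid.nodes:
        raise GridConstructionError(f"arrival node {arrival} not in grid")
    wind_at = _node_winds(grid, field, departure, departure_time, policy)
    t64 = as_utc64(departure_time)

    # heap entries: (time_s, n_edges, path); path tuples compare
    # lexicographically because Node is an ordered tuple.
    start = (0.0, 0, (departure,))
    heap = [start]
    settled: set[Node] = set()
    while heap:
        time_s, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled.add(node)
        if node == arrival:
            edge_times = []
            for a, b in zip(path[:-1], path[1:]):
                w = wind_at(a)
                edge_times.append(edge_travel_time((a.lat, a.lon), (b.lat, b.lon), w, policy))
            return RouteResult(
                total_time_h=time_s / 3600.0,
                path=path,
                per_edge_times_s=tuple(edge_times),
                variant=grid.variant,
                departure_time=t64,
            )
        w = wind_at(node)
        for nxt in grid.successors(node):
            if nxt in settled:
                continue
            dt = edge_travel_time((node.lat, node.lon), (nxt.lat, nxt.lon), w, policy)
            if dt is INFEASIBLE or not math.isfinite(dt):
                continue
            heapq.heappush(heap, (time_s + dt, hops + 1, path + (nxt,)))
    return RouteResult(
        total_time_h=math.inf,
        path=(),
        per_edge_times_s=(),
        variant=grid.variant,
        departure_time=t64,
    )


def arrival_node_for_dead_bird(history: Iterable) -> Node:
    """Arrival node for a crossing whose bird died en route.

    A bird that dies mid-desert never reveals its intended arrival node;
    adult godwits reuse Iberian staging sites faithfully, so the arrival
    node of the individual's most recent prior completed northward
    crossing stands in.  ``history`` is any iterable of objects with
    ``season``, ``departure_time`` and ``arrival_node`` attributes.
    Raises :class:`UnresolvableArrivalError` (callers exclude the crossing
    and log the reason) when no prior northward crossing completed.
    """
    priors = [
        c for c in history
        if getattr(c, "season", None) == "northward"
        and getattr(c, "arrival_node", None) is not None
    ]
    if not priors:
        raise UnresolvableArrivalError(
            "no prior completed northward crossing to supply an arrival node"
        )
    priors.sort(key=lambda c: as_utc64(c.departure_time))
    return priors[-1].arrival_node
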