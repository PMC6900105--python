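"""Geodesy and flight mechanics.

Great-circle distance/bearing on a spherical Earth, decomposition of the
horizontal wind into tailwind and crosswind relative to a track, the
drift-compensated groundspeed of a bird holding a constant airspeed, and
the travel time of a single graph edge.

All functions are pure; angles are degrees, speeds m/s, distances m,
times s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

EARTH_RADIUS_M = 6_371_000.0

#: Sentinel for an edge or groundspeed with no feasible forward progress.
#: It is +inf so that it can be used directly as an infinite edge weight.
INFEASIBLE = math.inf


@dataclass(frozen=True)
class AirspeedPolicy:
    """Constant-airspeed flight policy.

    The default of 18.05 m/s is a flapping-flight airspeed typical of a
    medium-sized shorebird on migration.
    """

    airspeed: float = 18.05

    def __post_init__(self) -> None:
        if not self.airspeed > 0:
            raise ValueError(f"airspeed must be positive, got {self.airspeed}")


def great_circle(p1: tuple[float, float], p2: tuple[float, float]) -> tuple[float, float]:
    """Haversine distance (m) and initial bearing (deg clockwise from N).

    Parameters are (lat, lon) pairs in degrees.  Identical points return
    (0.0, 0.0) by convention.
    """
    lat1, lon1 = math.radians(p1[0]), math.radians(p1[1])
    lat2, lon2 = math.radians(p2[0]), math.radians(p2[1])
    if p1 == p2:
        return 0.0, 0.0
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    dist = 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    bearing = math.degrees(math.atan2(y, x)) % 360.0
    return dist, bearing


def wind_components(u: float, v: float, track_bearing: float) -> tuple[float, float]:
    """Project the wind vector onto a track.

    Returns (tailwind, crosswind): the along-track component (positive =
    assisting) and the across-track component.  The projection is a pure
    rotation, so tailwind**2 + crosswind**2 == u**2 + v**2.
    """
    theta = math.radians(track_bearing)
    tailwind = u * math.sin(theta) + v * math.cos(theta)
    crosswind = u * math.cos(theta) - v * math.sin(theta)
    return tailwind, crosswind


def groundspeed(tailwind: float, crosswind: float, policy: AirspeedPolicy) -> float:
    """Drift-compensated groundspeed at constant airspeed.

    The bird offsets its heading so that the realized track equals the
    intended track; the along-track groundspeed is then

        g = tailwind + sqrt(airspeed**2 - crosswind**2).

    Returns INFEASIBLE when the crosswind is at least the airspeed (the
    track cannot be held) or when the net along-track speed is <= 0 (no
    forward progress).
    """
    a = policy.airspeed
    if abs(crosswind) >= a:
        return INFEASIBLE
    g = tailwind + math.sqrt(a * a - crosswind * crosswind)
    if g <= 0:
        return INFEASIBLE
    return g


def edge_travel_time(
    p1: tuple[float, float],
    p2: tuple[float, float],
    wind: tuple[float, float],
    policy: AirspeedPolicy,
) -> float:
    """Travel time (s) of the leg p1 -> p2 under wind (u, v) at p1.

    The wind is decomposed along the great-circle initial bearing of the
    leg.  Returns INFEASIBLE (inf) when the leg cannot be flown; a purely
    vertical pair (identical horizontal coordinates) is rejected because a
    zero-length edge would have zero cost.
    """
    if (p1[0], p1[1]) == (p2[0], p2[1]):
        raise ValueError("purely vertical edge: p1 and p2 share lat/lon")
    dist, bearing = great_circle((p1[0], p1[1]), (p2[0], p2[1]))
    tailwind, crosswind = wind_components(wind[0], wind[1], bearing)
    g = groundspeed(tailwind, crosswind, policy)
    if not math.isfinite(g):
        return INFEASIBLE
    return dist / g
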