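"""End-to-end orchestration: fixes -> crossings -> routes -> model inputs.

Thin glue over the core modules; the CLI and the analysis scripts drive
everything through these helpers.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .kinematics import AirspeedPolicy
from .route_graph import (
    GridConstructionError,
    Node,
    NodeGrid,
    UnresolvableArrivalError,
    arrival_node_for_dead_bird,
    build_grid,
    minimal_flight_time,
    restrict_informed,
)
from .tracks_io import (
    Crossing,
    diagnose_fate,
    quality_filter,
    relative_departure_date,
    segment_crossings,
)
from .wind_model import WindField, as_utc64

logger = logging.getLogger(__name__)


def pick_field(fields: Iterable[WindField], t) -> WindField:
    """The wind field whose analysis window is closest to time t."""
    t64 = as_utc64(t)
    best, best_d = None, None
    for f in fields:
        if f.times[0] <= t64 <= f.times[-1]:
            return f
        d = min(abs((f.times[0] - t64) / np.timedelta64(1, "s")),
                abs((f.times[-1] - t64) / np.timedelta64(1, "s")))
        if best_d is None or d < best_d:
            best, best_d = f, d
    if best is None:
        raise ValueError("no wind fields supplied")
    return best


def classify_crossings(
    fixes: pd.DataFrame,
    desert_mask: Polygon,
    resolution: float = 0.4,
    levels: Sequence[float] = (925.0, 850.0, 750.0, 650.0),
    resightings: dict[str, bool] | None = None,
) -> list[Crossing]:
    """Quality-filter fixes, segment them per individual, and classify
    each crossing's fate from the transmitter diagnostics."""
    resightings = resightings or {}
    fixes = quality_filter(fixes)
    out: list[Crossing] = []
    for ind, track in fixes.groupby("id", sort=True):
        crossings = segment_crossings(
            track.reset_index(drop=True), desert_mask,
            resolution=resolution, levels=levels,
        )
        for k, c in enumerate(crossings):
            if c.arrival_time is not None:
                post = track[track["timestamp"] > c.arrival_time]
            else:
                post = track[track["timestamp"] > c.fixes["timestamp"].iloc[-1]]
            prior = track[track["timestamp"] < c.fixes["timestamp"].iloc[0]]
            c.fate, c.fate_rule = diagnose_fate(
                c, post, resighted=resightings.get(ind, False),
                prior_fixes=prior if len(prior) else None,
            )
            out.append(c)
    return out


def resolve_arrivals(out: Sequence[Crossing]) -> list[Crossing]:
    """Resolve arrival nodes for crossings that never revealed one (the
    bird died mid-desert), using the individual's most recent prior
    completed northward crossing; crossings without one are excluded
    with a logged reason."""
    by_ind: dict[str, list[Crossing]] = {}
    for c in out:
        by_ind.setdefault(c.individual_id, []).append(c)
    resolved: list[Crossing] = []
    for c in out:
        if c.arrival_node is None:
            history = [
                h for h in by_ind[c.individual_id]
                if h.arrival_node is not None
                and as_utc64(h.departure_time) < as_utc64(c.departure_time)
            ]
            try:
                c.arrival_node = arrival_node_for_dead_bird(history)
            except UnresolvableArrivalError:
                logger.warning(
                    "excluding crossing of %s departing %s: died and no prior "
                    "completed northward crossing to supply an arrival node",
                    c.individual_id, c.departure_time,
                )
                continue
        resolved.append(c)
    return resolved


def extract_crossings(
    fixes: pd.DataFrame,
    desert_mask: Polygon,
    resolution: float = 0.4,
    levels: Sequence[float] = (925.0, 850.0, 750.0, 650.0),
    resightings: dict[str, bool] | None = None,
) -> list[Crossing]:
    """Full ingestion: classify crossings, then resolve arrival nodes."""
    return resolve_arrivals(
        classify_crossings(
            fixes, desert_mask, resolution=resolution, levels=levels,
            resightings=resightings,
        )
    )


def simulate_routes(
    crossings: Sequence[Crossing],
    fields: Sequence[WindField],
    corridor: Polygon,
    resolution: float = 0.4,
    levels: Sequence[float] = (925.0, 850.0, 750.0, 650.0),
    buffer: float = 0.5,
    policy: AirspeedPolicy = AirspeedPolicy(),
    variants: Sequence[str] = ("uninformed", "informed"),
) -> pd.DataFrame:
    """Minimal flight times for each crossing under each grid variant.

    Returns one row per crossing with time_uninformed/time_informed (h),
    covariates, and reachability flags.
    """
    grid = build_grid(corridor, resolution=resolution, levels=levels)
    rows = []
    for k, c in enumerate(crossings):
        field = pick_field(fields, c.departure_time)
        row = {
            "crossing_id": f"{c.individual_id}-{k}",
            "individual": c.individual_id,
            "season": c.season,
            "tag_type": c.tag_type,
            "fate": c.fate,
            "departure_time": c.departure_time,
            "departure_doy": c.departure_doy,
            "n_in_flight_fixes": len(c.fixes),
        }
        for variant in variants:
            if variant == "uninformed":
                g = grid
            else:
                g = restrict_informed(
                    grid,
                    list(zip(c.fixes["lat"], c.fixes["lon"])),
                    buffer=buffer,
                    departure=(c.departure_node.lat, c.departure_node.lon),
                    arrival=(c.arrival_node.lat, c.arrival_node.lon),
                )
            try:
                res = minimal_flight_time(
                    g, field, c.departure_node, c.arrival_node,
                    c.departure_time, policy,
                )
                row[f"time_{variant}"] = res.total_time_h
                row[f"n_edges_{variant}"] = len(res.per_edge_times_s)
                row[f"reachable_{variant}"] = res.reachable
            except GridConstructionError as err:
                logger.warning("crossing %s (%s): %s", row["crossing_id"], variant, err)
                row[f"time_{variant}"] = np.inf
                row[f"n_edges_{variant}"] = 0
                row[f"reachable_{variant}"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def attach_relative_departure(routes: pd.DataFrame) -> pd.DataFrame:
    """Add the relative-departure-date covariate (days) to a routes table.

    Relative to the mean northward departure day-of-year over the table's
    whole reference window.
    """
    routes = routes.copy()
    north = routes[routes["season"] == "northward"]
    if len(north) == 0:
        raise ValueError("no northward crossings to define the reference mean")
    mean_doy = float(north["departure_doy"].mean())
    routes["relative_departure_days"] = np.where(
        routes["season"] == "northward",
        routes["departure_doy"] - mean_doy,
        np.nan,
    )
    return routes
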