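"""Argos-style track ingestion, crossing segmentation and fate diagnosis.

Satellite transmitters on individual birds yield sparse, duty-cycled
location fixes, each with an Argos location-quality class and two sensor
channels (an activity counter on 9.5 g tags, a temperature sensor on 5 g
tags).  This module reads fix tables, applies the quality-class retention
rule, cuts a track into desert crossings against a desert-mask polygon,
diagnoses the bird's fate from transmitter behaviour after the crossing,
and computes the relative-departure-date covariate used by the mortality
model.

Fix tables are pandas DataFrames with columns
``id, timestamp, lat, lon, lc, activity, temperature, tag_type``
(one row per fix, timestamps ISO-8601 UTC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .route_graph import Node, snap_to_lattice

logger = logging.getLogger(__name__)

#: Argos location-quality classes kept for analysis; class Z is discarded.
RETAINED_QUALITY_CLASSES = ("3", "2", "1", "0", "A", "B")

FIX_COLUMNS = ["id", "timestamp", "lat", "lon", "lc", "activity", "temperature", "tag_type"]

#: Activity is "constant" when its post-event variance falls below this
#: fraction of the tag's lifetime variance (9.5 g death rule).
ACTIVITY_VARIANCE_RATIO = 1e-6
#: Temperature is "diurnal" when the 24-h harmonic amplitude exceeds this
#: multiple of the residual SD (5 g death rule).
DIURNAL_AMPLITUDE_RATIO = 3.0
#: A transmitter silent for this long after its last in-flight fix "never
#: turned on again" (cessation death rule).
SILENCE_DAYS = 365
#: Post-event window over which the sensor rules are evaluated.
FATE_WINDOW_DAYS = 7.0
#: An entry gap longer than this marks the departure snap low-confidence.
ENTRY_GAP_HOURS = 6.0


class EmptyReferenceError(ValueError):
    """The relative-departure-date reference set is empty."""


@dataclass
class Crossing:
    """One individual x season desert transit."""

    individual_id: str
    season: str                      # "southward" | "northward"
    tag_type: str                    # "5g" | "9.5g"
    departure_node: Node
    departure_time: pd.Timestamp
    arrival_node: Node | None        # None until resolved for dead birds
    arrival_time: pd.Timestamp | None
    fixes: pd.DataFrame              # in-flight fixes, time-ordered
    fate: str = "unknown"            # "survived" | "died" | "unknown"
    fate_rule: str = ""              # which diagnostic rule fired, if any
    low_confidence_departure: bool = False

    @property
    def completed(self) -> bool:
        return self.arrival_time is not None

    @property
    def departure_doy(self) -> int:
        return int(self.departure_time.dayofyear)


def read_fixes(path) -> pd.DataFrame:
    """Read a fix CSV, parse timestamps as UTC, sort per individual."""
    df = pd.read_csv(path, dtype={"id": str, "lc": str, "tag_type": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.sort_values(["id", "timestamp"], kind="stable").reset_index(drop=True)
    _check_monotone(df)
    return df


def write_fixes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def _check_monotone(df: pd.DataFrame) -> None:
    for ind, sub in df.groupby("id", sort=False):
        ts = sub["timestamp"].to_numpy()
        if len(ts) > 1 and not (np.diff(ts) > np.timedelta64(0, "s")).all():
            raise ValueError(f"timestamps not strictly increasing for individual {ind}")


def quality_filter(fixes: pd.DataFrame) -> pd.DataFrame:
    """Retain quality classes 3/2/1/0/A/B; drop Z and anything unlisted.

    Order-preserving and idempotent.
    """
    keep = fixes["lc"].astype(str).isin(RETAINED_QUALITY_CLASSES)
    return fixes.loc[keep].reset_index(drop=True)


def segment_crossings(
    track: pd.DataFrame,
    desert_mask: Polygon,
    resolution: float = 0.4,
    levels: Sequence[float] = (925.0, 850.0, 750.0, 650.0),
) -> list[Crossing]:
    """Cut one individual's track into desert crossings.

    A crossing is a maximal run of fixes inside the desert mask.  The
    departure node/time is the last fix before entry snapped to the
    lattice; the arrival node is the first fix after exit (None while the
    track never exits, i.e. the transmitter stopped mid-desert).  Fixes
    inside the mask are the crossing's in-flight fixes.  A duty-cycle gap
    longer than ``ENTRY_GAP_HOURS`` between the pre-entry fix and the
    first in-flight fix flags the departure snap as low-confidence.
    Departure/arrival nodes sit on the lowest-altitude (highest-pressure)
    configured layer.
    """
    levels = tuple(sorted((float(x) for x in levels), reverse=True))
    ground = levels[0]
    track = track.sort_values("timestamp", kind="stable").reset_index(drop=True)
    pts = shapely.points(track["lon"].to_numpy(), track["lat"].to_numpy())
    inside = shapely.covers(desert_mask, pts)
    crossings: list[Crossing] = []
    i, n = 0, len(track)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j < n and inside[j]:
            j += 1
        # run [i, j) is inside the mask
        if i == 0:
            logger.warning(
                "track for %s starts inside the desert mask; run skipped",
                track["id"].iloc[0],
            )
            i = j
            continue
        dep_fix = track.iloc[i - 1]
        in_flight = track.iloc[i:j].reset_index(drop=True)
        arr_fix = track.iloc[j] if j < n else None
        dep_lat, dep_lon = snap_to_lattice(dep_fix["lat"], dep_fix["lon"], resolution)
        departure_node = Node(dep_lat, dep_lon, ground)
        if arr_fix is not None:
            arr_lat, arr_lon = snap_to_lattice(arr_fix["lat"], arr_fix["lon"], resolution)
            arrival_node = Node(arr_lat, arr_lon, ground)
            arrival_time = arr_fix["timestamp"]
            end_lat = arr_fix["lat"]
        else:
            arrival_node = None
            arrival_time = None
            end_lat = in_flight["lat"].iloc[-1]
        season = "southward" if end_lat < dep_fix["lat"] else "northward"
        gap_h = (in_flight["timestamp"].iloc[0] - dep_fix["timestamp"]) / pd.Timedelta(hours=1)
        crossings.append(
            Crossing(
                individual_id=str(dep_fix["id"]),
                season=season,
                tag_type=str(dep_fix["tag_type"]),
                departure_node=departure_node,
                departure_time=dep_fix["timestamp"],
                arrival_node=arrival_node,
                arrival_time=arrival_time,
                fixes=in_flight,
                low_confidence_departure=bool(gap_h > ENTRY_GAP_HOURS),
            )
        )
        i = j
    return crossings


def segment_crossing(
    track: pd.DataFrame, desert_mask: Polygon, **kwargs
) -> Crossing | None:
    """First desert crossing in a track, or None if it never enters the mask."""
    found = segment_crossings(track, desert_mask, **kwargs)
    return found[0] if found else None


def _diurnal_amplitude_ratio(times: pd.Series, temps: np.ndarray) -> float:
    """Amplitude of the 24-h harmonic relative to the residual SD."""
    if len(temps) < 6:
        return 0.0
    t_h = (times - times.iloc[0]) / pd.Timedelta(hours=1)
    omega = 2 * np.pi / 24.0
    X = np.column_stack([np.ones(len(temps)), np.sin(omega * t_h), np.cos(omega * t_h)])
    beta, *_ = np.linalg.lstsq(X, temps, rcond=None)
    amplitude = float(np.hypot(beta[1], beta[2]))
    resid = temps - X @ beta
    sd = float(np.std(resid, ddof=3)) if len(temps) > 3 else float(np.std(resid))
    if sd <= 0:
        return np.inf if amplitude > 0 else 0.0
    return amplitude / sd


def _trailing_stationary(series: pd.DataFrame, radius_deg: float = 0.2) -> pd.DataFrame:
    """Maximal suffix of fixes within ``radius_deg`` of the final position.

    A carcass transmits from one spot; a flying or staging-then-moving
    bird does not stay put mid-desert.  The suffix is the candidate
    post-death window.
    """
    lat_end = series["lat"].iloc[-1]
    lon_end = series["lon"].iloc[-1]
    close = (
        (series["lat"] - lat_end).abs().to_numpy() <= radius_deg
    ) & ((series["lon"] - lon_end).abs().to_numpy() <= radius_deg)
    # last index where close is False marks the start of the suffix
    not_close = np.flatnonzero(~close)
    start = (not_close[-1] + 1) if len(not_close) else 0
    return series.iloc[start:]


def _sensor_rule(window: pd.DataFrame, tag_type: str, prior_fixes: pd.DataFrame) -> str:
    """Which sensor death rule (if any) fires on an evaluation window."""
    if len(window) == 0:
        return ""
    # trailing FATE_WINDOW_DAYS: clear of the transient around the event
    t1 = window["timestamp"].iloc[-1]
    window = window[window["timestamp"] >= t1 - pd.Timedelta(days=FATE_WINDOW_DAYS)]
    if tag_type == "9.5g" and len(window) >= 3:
        life_var = float(np.nanvar(prior_fixes["activity"].to_numpy(dtype=float)))
        win_var = float(np.nanvar(window["activity"].to_numpy(dtype=float)))
        if life_var > 0 and win_var < ACTIVITY_VARIANCE_RATIO * life_var:
            return "activity_constant"
    if tag_type == "5g" and len(window) >= 6:
        ratio = _diurnal_amplitude_ratio(
            window["timestamp"].reset_index(drop=True),
            window["temperature"].to_numpy(dtype=float),
        )
        if ratio > DIURNAL_AMPLITUDE_RATIO:
            return "temperature_diurnal"
    return ""


#: A transmitter still active this long past its last movement is treated
#: as transmitting from a carcass, not as a bout interrupted mid-air.
_STATIONARY_MIN_DAYS = 2.0


def diagnose_fate(
    crossing: Crossing,
    post_fixes: pd.DataFrame,
    resighted: bool = False,
    prior_fixes: pd.DataFrame | None = None,
) -> tuple[str, str]:
    """Fate plus the diagnostic rule that fired (empty string if none).

    Three death rules: (1) a 9.5 g tag whose activity sensor goes
    constant (variance below ``ACTIVITY_VARIANCE_RATIO`` x lifetime
    variance over the post-event window); (2) a 5 g tag whose temperature
    sensor starts following a diurnal rhythm (24-h harmonic amplitude >
    ``DIURNAL_AMPLITUDE_RATIO`` x residual SD) — a carcass tracks ambient
    temperature while a living bird buffers it; (3) a transmitter that
    stops transmitting within a migratory bout and never turns on again
    (no fix within ``SILENCE_DAYS``).  For an uncompleted crossing the
    sensor rules are evaluated on the trailing stationary segment of the
    transmissions (the transmitter keeps duty-cycling on the carcass);
    for a completed crossing, on the first post-arrival window.  A later
    resighting overrides any death rule: the transmitter failed, the bird
    did not.  ``prior_fixes`` (default: the in-flight fixes) supply the
    lifetime activity baseline.
    """
    if prior_fixes is None:
        prior_fixes = crossing.fixes
    parts = [df for df in (crossing.fixes, post_fixes) if len(df)]
    if parts:
        series = pd.concat(parts, ignore_index=True)
        series = series.sort_values("timestamp", kind="stable").reset_index(drop=True)
    else:
        series = crossing.fixes
    post = post_fixes.sort_values("timestamp", kind="stable").reset_index(drop=True)

    rule = ""
    if crossing.completed:
        # only the window just after arrival is diagnostic for *this*
        # crossing; later records belong to later crossings
        horizon = crossing.arrival_time + pd.Timedelta(days=2 * FATE_WINDOW_DAYS)
        rule = _sensor_rule(
            post[post["timestamp"] <= horizon], crossing.tag_type, prior_fixes
        )
    elif len(series):
        suffix = _trailing_stationary(series)
        span_d = (
            (suffix["timestamp"].iloc[-1] - suffix["timestamp"].iloc[0])
            / pd.Timedelta(days=1) if len(suffix) else 0.0
        )
        if span_d >= _STATIONARY_MIN_DAYS:
            prior = series.iloc[: len(series) - len(suffix)]
            if len(prior) < 5:  # too short for a lifetime baseline
                prior = prior_fixes
            rule = _sensor_rule(suffix, crossing.tag_type, prior)
        if rule == "":
            # transmissions ceased mid-bout; "never turned on again" means
            # no fix within SILENCE_DAYS of the cessation
            last = crossing.fixes["timestamp"].iloc[-1] if len(crossing.fixes) else None
            later = post[post["timestamp"] > last] if last is not None else post
            if len(later) == 0 and span_d < _STATIONARY_MIN_DAYS:
                rule = "ceased_transmitting"
            elif len(later) > 0:
                silence = (later["timestamp"].iloc[0] - last) / pd.Timedelta(days=1)
                if silence > SILENCE_DAYS:
                    rule = "ceased_transmitting"

    if rule and resighted:
        logger.warning(
            "fate rule %s fired for %s but the bird was later resighted; "
            "classifying as survived (transmitter failure)",
            rule, crossing.individual_id,
        )
        return "survived", ""
    if rule:
        return "died", rule
    if crossing.completed and (len(post) > 0 or resighted):
        return "survived", ""
    return "unknown", ""


def classify_fate(
    crossing: Crossing,
    post_fixes: pd.DataFrame,
    resighted: bool = False,
    prior_fixes: pd.DataFrame | None = None,
) -> str:
    """Fate of the bird: "survived", "died" or "unknown".

    See :func:`diagnose_fate` for the diagnostic rules; this wrapper
    drops the fired-rule detail.
    """
    fate, _ = diagnose_fate(crossing, post_fixes, resighted, prior_fixes)
    return fate


def relative_departure_date(
    crossing: Crossing, reference_crossings: Iterable[Crossing]
) -> float:
    """Departure day-of-year minus the reference-set mean departure DOY.

    The reference set is the pooled northward crossings of the study
    window (the multi-year mean departure date from Africa).
    """
    ref = [c.departure_doy for c in reference_crossings if c.season == "northward"]
    if not ref:
        raise EmptyReferenceError("no northward crossings in the reference set")
    return float(crossing.departure_doy - np.mean(ref))


def crossings_to_frame(crossings: Sequence[Crossing]) -> pd.DataFrame:
    """Flatten crossings to the CSV layout consumed by the route CLI."""
    rows = []
    for k, c in enumerate(crossings):
        rows.append(
            {
                "crossing_id": f"{c.individual_id}-{k}",
                "individual_id": c.individual_id,
                "season": c.season,
                "tag_type": c.tag_type,
                "departure_lat": c.departure_node.lat,
                "departure_lon": c.departure_node.lon,
                "departure_level": c.departure_node.level,
                "departure_time": c.departure_time,
                "arrival_lat": c.arrival_node.lat if c.arrival_node else np.nan,
                "arrival_lon": c.arrival_node.lon if c.arrival_node else np.nan,
                "arrival_level": c.arrival_node.level if c.arrival_node else np.nan,
                "fate": c.fate,
                "n_in_flight_fixes": len(c.fixes),
                "low_confidence_departure": c.low_confidence_departure,
            }
        )
    return pd.DataFrame(rows)
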