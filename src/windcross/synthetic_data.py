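"""Synthetic cohorts: wind fields, duty-cycled tracks, and fates.

Generates complete stand-ins for the study's inputs with known
ground-truth parameters, so every pipeline stage has a recovery target:

* paired trade-wind fields for the two migration seasons (the same
  north-easterly trades assist the southward crossing and oppose the
  northward one),
* per individual x season, a great-circle-plus-jitter trajectory flown
  at constant airspeed through the sampled winds, subsampled by the
  transmitter duty cycle into sparse Argos-style fixes,
* in-flight mortality drawn from a logistic model on the bird's realized
  (truth-side) flight time, with the transmitter's post-death behaviour
  chosen to trigger exactly one fate-diagnostic rule.

The truth table records every generating parameter and realized
quantity per crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import box

from .kinematics import AirspeedPolicy, great_circle, groundspeed, wind_components
from .wind_model import (
    SyntheticWindConfig,
    WindField,
    analysis_times,
    generate_synthetic_wind,
    sample_wind,
)

#: Default simulation corridor (lat0, lat1, lon0, lon1): a narrow
#: desert-crossing band, ~1800 km staging-to-staging.
DEFAULT_EXTENT = (14.8, 32.4, -8.0, -4.8)
#: Desert-mask latitude band inside the corridor; the strips between the
#: band and the corridor edge are the staging zones.
DESERT_BAND = (17.6, 29.6)

DUTY_CYCLES = {"8/24": (8.0, 24.0), "10/48": (10.0, 48.0)}

_LC_CLASSES = np.array(["3", "2", "1", "0", "A", "B", "Z"])
_LC_PROBS = np.array([0.05, 0.08, 0.12, 0.20, 0.25, 0.25, 0.05])


def default_corridor():
    lat0, lat1, lon0, lon1 = DEFAULT_EXTENT
    return box(lon0, lat0, lon1, lat1)  # shapely: x=lon, y=lat


def default_desert_mask():
    _, _, lon0, lon1 = DEFAULT_EXTENT
    return box(lon0 - 5.0, DESERT_BAND[0], lon1 + 5.0, DESERT_BAND[1])


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of a synthetic tracking cohort.

    Mortality applies to northward crossings only (southward crossings in
    the emulated system are essentially safe):
    logit(P(die)) = mortality_intercept + mortality_slope * flight_time_h,
    with the *realized* truth-side flight time, so downstream estimation
    error is honestly present in recovery tests.
    """

    n_individuals: int = 60
    n_years: int = 1
    seasons: tuple[str, ...] = ("northward", "southward")
    p_tag_5g: float = 0.075                 # share of 5 g (temperature) tags
    p_duty_10_48: float = 0.3               # share of 9.5 g tags on 10 h/48 h duty
    fix_rate_per_hour: float = 1.0          # fixes per hour while transmitting
    mortality_intercept: float = -10.0
    mortality_slope: float = 0.25           # per hour of realized flight time
    departure_doy: dict = field(
        default_factory=lambda: {"northward": 105, "southward": 288}
    )
    departure_doy_sd: float = 3.0
    base_year: int = 2016
    cross_track_jitter_deg: float = 0.15
    p_sensor_rule: float = 0.7              # dead 9.5g->rule1, 5g->rule2; else rule 3
    min_groundspeed: float = 4.0            # m/s floor (a bird cannot hover)
    airspeed: float = 18.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_tag_5g, self.p_duty_10_48, self.p_sensor_rule):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


def generate_seasonal_scenario(
    cfg: CohortConfig,
    trade: SyntheticWindConfig = SyntheticWindConfig(),
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    window_days: int = 24,
) -> dict[str, list[WindField]]:
    """Paired per-season wind fields over the corridor.

    Both seasons carry the same NE-trade mean flow (scaled by
    ``trade.seasonal_reversal``), so the trades assist the southward
    crossing and oppose the northward one — the qualitative seasonal
    contrast the pipeline must detect; a reversal factor of -1 turns the
    trades around and flips the contrast exactly.  One field is generated
    per study year (cfg.n_years), each a contiguous 6-hourly window
    around that year's mean departure date.
    """
    lat0, lat1, lon0, lon1 = extent
    fields: dict[str, list[WindField]] = {}
    for i, season in enumerate(("southward", "northward")):
        per_year = []
        for year in range(cfg.n_years):
            doy = cfg.departure_doy[season]
            calendar_year = cfg.base_year + year + (1 if season == "northward" else 0)
            start = (
                np.datetime64(f"{calendar_year}-01-01")
                + np.timedelta64(int(doy) - 10, "D")
            )
            scfg = SyntheticWindConfig(
                mean_trade_u=trade.mean_trade_u,
                mean_trade_v=trade.mean_trade_v,
                shear_profile=trade.shear_profile,
                temporal_sd=trade.temporal_sd,
                temporal_autocorr=trade.temporal_autocorr,
                seasonal_reversal=trade.seasonal_reversal,
                seed=trade.seed + 1000 * year + i,
            )
            times = analysis_times(start.astype("datetime64[s]"), window_days * 4)
            per_year.append(generate_synthetic_wind(scfg, (lat0, lat1, lon0, lon1), times))
        fields[season] = per_year
    return fields


def _duty_cycle_times(rng, start, end, d_on_h, d_off_h, rate_per_h):
    """Transmission timestamps between start and end under a duty cycle."""
    cycle = d_on_h + d_off_h
    phase = float(rng.uniform(0, cycle))
    span_h = (end - start) / pd.Timedelta(hours=1)
    times = []
    t = -phase
    while t < span_h:
        n_fix = max(1, int(round(d_on_h * rate_per_h)))
        offs = np.sort(rng.uniform(0, d_on_h, size=n_fix))
        for o in offs:
            if 0 <= t + o < span_h:
                times.append(t + o)
        t += cycle
    times = np.unique(np.round(np.asarray(times), 4))
    return start + pd.to_timedelta(times, unit="h")


def _trajectory(rng, cfg, dep, arr, n_seg=72):
    """Waypoints of a jittered great-circle-ish track (lat, lon arrays)."""
    f = np.linspace(0.0, 1.0, n_seg + 1)
    lat = dep[0] + f * (arr[0] - dep[0])
    lon = dep[1] + f * (arr[1] - dep[1])
    # smooth cross-track jitter: anchors interpolated along the track,
    # pinned to zero at the endpoints
    n_anchor = 8
    anchors = rng.normal(0.0, cfg.cross_track_jitter_deg, size=n_anchor)
    anchors[0] = anchors[-1] = 0.0
    lon = lon + np.interp(f, np.linspace(0, 1, n_anchor), anchors)
    return lat, lon


def _fly(cfg, field, level, lat, lon, departure_time, policy):
    """Integrate travel time along the waypoints; returns cumulative hours."""
    cum_h = [0.0]
    t = pd.Timestamp(departure_time)
    for k in range(len(lat) - 1):
        dist, bearing = great_circle((lat[k], lon[k]), (lat[k + 1], lon[k + 1]))
        u, v = sample_wind(field, lat[k], lon[k], level, t.to_datetime64())
        tw, cw = wind_components(u, v, bearing)
        g = groundspeed(tw, cw, policy)
        if not np.isfinite(g) or g < cfg.min_groundspeed:
            g = cfg.min_groundspeed
        dt_h = dist / g / 3600.0
        cum_h.append(cum_h[-1] + dt_h)
        t = t + pd.Timedelta(hours=dt_h)
    return np.asarray(cum_h)


def _best_level(cfg, field, dep, arr, departure_time, policy):
    """The pressure level with the best tailwind toward the destination
    sampled at departure — a mildly wind-smart altitude choice."""
    _, bearing = great_circle(dep, arr)
    best, best_g = None, -np.inf
    for level in field.levels:
        u, v = sample_wind(field, dep[0], dep[1], level, departure_time)
        g = groundspeed(*wind_components(u, v, bearing), policy)
        g = -np.inf if not np.isfinite(g) else g
        if g > best_g:
            best, best_g = level, g
    return best if best is not None else field.levels[0]


def generate_cohort(
    cfg: CohortConfig,
    wind: WindField | dict[str, WindField],
    corridor=None,
    with_fixes: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the fix table and truth table of a tracking cohort.

    ``wind`` is a single field or a mapping season -> field (see
    :func:`generate_seasonal_scenario`).  Returns ``(fixes, truth)``:
    ``fixes`` holds one row per transmitted location with columns
    id/timestamp/lat/lon/lc/activity/temperature/tag_type; ``truth`` one
    row per crossing with every generating parameter and realized
    quantity.  Deterministic under the config seed.  ``with_fixes=False``
    skips the fix table (the truth table is unchanged) for analyses that
    only need per-crossing ground truth.
    """
    if corridor is None:
        corridor = default_corridor()
    if isinstance(wind, dict):
        fields = {
            s: (f if isinstance(f, list) else [f] * cfg.n_years)
            for s, f in wind.items()
        }
    else:
        fields = {s: [wind] * cfg.n_years for s in cfg.seasons}
    for season in cfg.seasons:
        if season not in fields or len(fields[season]) < cfg.n_years:
            raise ValueError(f"need {cfg.n_years} wind field(s) for season '{season}'")
    minx, miny, maxx, maxy = corridor.bounds
    for season, per_year in fields.items():
        for f in per_year:
            if not (f.lats.min() <= miny and f.lats.max() >= maxy
                    and f.lons.min() <= minx and f.lons.max() >= maxx):
                raise ValueError(f"wind field for '{season}' does not cover the corridor")

    # two independent streams so the truth table is identical whether or
    # not the (much noisier) fix table is generated
    rng = np.random.default_rng([cfg.seed, 0])
    rng_fix = np.random.default_rng([cfg.seed, 1])
    policy = AirspeedPolicy(cfg.airspeed)
    south_stage = (miny + 0.6, 0.5 * (minx + maxx))   # staging strips inside the
    north_stage = (maxy - 0.6, 0.5 * (minx + maxx))   # corridor, outside the mask

    fix_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(cfg.n_individuals):
        ind = f"bird{i:03d}"
        tag = "5g" if rng.random() < cfg.p_tag_5g else "9.5g"
        if tag == "5g":
            duty = "8/24"
        else:
            duty = "10/48" if rng.random() < cfg.p_duty_10_48 else "8/24"
        d_on, d_off = DUTY_CYCLES[duty]
        activity_base = rng_fix.uniform(20, 200)
        alive = True
        last_end = None

        # one migration cycle per study year: southward in autumn of
        # calendar year base+y, northward the following spring
        year_seasons = [
            (year, season)
            for year in range(cfg.n_years)
            for season in ("southward", "northward")
            if season in cfg.seasons
        ]

        for year, season in year_seasons:
            if not alive:
                break
            field_s = fields[season][year]
            calendar_year = cfg.base_year + year + (1 if season == "northward" else 0)
            doy = rng.normal(cfg.departure_doy[season], cfg.departure_doy_sd)
            base = pd.Timestamp(f"{calendar_year}-01-01", tz="UTC")
            departure_time = base + pd.Timedelta(days=float(doy) - 1 + rng.uniform(0, 1))
            if season == "southward":
                dep, arr = north_stage, south_stage
            else:
                dep, arr = south_stage, north_stage
            # jitter endpoints a little within the corridor width
            dep = (dep[0], float(np.clip(dep[1] + rng.normal(0, 0.3), minx + 0.3, maxx - 0.3)))
            arr = (arr[0], float(np.clip(arr[1] + rng.normal(0, 0.3), minx + 0.3, maxx - 0.3)))

            lat_w, lon_w = _trajectory(rng, cfg, dep, arr)
            level = _best_level(cfg, field_s, dep, arr, departure_time.to_datetime64(), policy)
            cum_h = _fly(cfg, field_s, level, lat_w, lon_w, departure_time, policy)
            flight_h = float(cum_h[-1])
            arrival_time = departure_time + pd.Timedelta(hours=flight_h)

            died = False
            if season == "northward":
                p_die = float(expit(cfg.mortality_intercept + cfg.mortality_slope * flight_h))
                died = bool(rng.random() < p_die)
            else:
                p_die = 0.0
            death_rule = ""
            death_frac = np.nan
            if died:
                alive = False
                death_frac = float(rng.uniform(0.15, 0.85))
                if rng.random() < cfg.p_sensor_rule:
                    death_rule = "activity_constant" if tag == "9.5g" else "temperature_diurnal"
                else:
                    death_rule = "ceased_transmitting"
            death_time = (
                departure_time + pd.Timedelta(hours=death_frac * flight_h) if died else None
            )

            # transmission window: 3 d of staging before departure; after the
            # crossing, 18 d at the destination (alive) or at the carcass
            # (sensor death rules); nothing after a cessation death.
            t_start = departure_time - pd.Timedelta(days=3)
            if not died:
                t_end = arrival_time + pd.Timedelta(days=18)
            elif death_rule == "ceased_transmitting":
                t_end = death_time
            else:
                t_end = death_time + pd.Timedelta(days=18)
            if with_fixes:
                stamps = _duty_cycle_times(
                    rng_fix, t_start, t_end, d_on, d_off, cfg.fix_rate_per_hour
                )
                hours_from_dep = (stamps - departure_time) / pd.Timedelta(hours=1)
                n_flight_fixes = 0
            else:
                stamps, hours_from_dep = [], []
                n_flight_fixes = -1  # not realized without a fix table
            for ts, h in zip(stamps, hours_from_dep):
                if h < 0:
                    plat, plon = dep
                    phase = "staging"
                elif died and h >= death_frac * flight_h:
                    k = np.searchsorted(cum_h, death_frac * flight_h)
                    k = min(k, len(lat_w) - 1)
                    plat, plon = lat_w[k], lon_w[k]
                    phase = "dead"
                elif h <= flight_h:
                    plat = float(np.interp(h, cum_h, lat_w))
                    plon = float(np.interp(h, cum_h, lon_w))
                    phase = "flight"
                    n_flight_fixes += 1
                else:
                    plat, plon = arr
                    phase = "post"
                # location scatter and quality class
                plat += rng_fix.normal(0, 0.03)
                plon += rng_fix.normal(0, 0.03)
                lc = str(rng_fix.choice(_LC_CLASSES, p=_LC_PROBS))
                if tag == "9.5g":
                    if phase == "dead":
                        activity = activity_base  # sensor frozen on the carcass
                    else:
                        activity = activity_base + rng_fix.uniform(-15, 15)
                    temperature = np.nan
                else:
                    activity = np.nan
                    if phase == "dead":
                        hod = ts.hour + ts.minute / 60.0
                        temperature = 28.0 + 9.0 * np.sin(2 * np.pi * (hod - 8.0) / 24.0)
                        temperature += rng_fix.normal(0, 0.3)
                    else:
                        temperature = 39.5 + rng_fix.normal(0, 0.5)  # buffered body temp
                fix_rows.append(
                    {
                        "id": ind,
                        "timestamp": ts,
                        "lat": float(plat),
                        "lon": float(plon),
                        "lc": lc,
                        "activity": float(activity) if np.isfinite(activity) else np.nan,
                        "temperature": float(temperature) if np.isfinite(temperature) else np.nan,
                        "tag_type": tag,
                    }
                )

            truth_rows.append(
                {
                    "individual_id": ind,
                    "year": cfg.base_year + year,
                    "season": season,
                    "tag_type": tag,
                    "duty_cycle": duty,
                    "flight_level_mb": float(level),
                    "departure_time": departure_time,
                    "departure_lat": dep[0],
                    "departure_lon": dep[1],
                    "arrival_lat": arr[0],
                    "arrival_lon": arr[1],
                    "realized_flight_time_h": flight_h,
                    "p_die": p_die,
                    "died": int(died),
                    "death_rule": death_rule,
                    "death_frac": death_frac,
                    "n_in_flight_fixes": n_flight_fixes,
                }
            )
            last_end = t_end

    fixes = pd.DataFrame(fix_rows)
    if len(fixes):
        fixes = fixes.sort_values(["id", "timestamp"], kind="stable").reset_index(drop=True)
        # enforce strictly increasing stamps per individual (rounding can tie)
        fixes = fixes.drop_duplicates(subset=["id", "timestamp"]).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return fixes, truth
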