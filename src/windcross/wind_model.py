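"""4D atmospheric wind fields.

A :class:`WindField` holds eastward (u) and northward (v) wind components
on a regular time x pressure-level x lat x lon grid, mirroring a
reanalysis product with 6-hourly analysis times (0:00/6:00/12:00/18:00
UTC).  The module reads/writes a NetCDF-style gridded format, answers
nearest-neighbour point queries, and synthesizes trade-wind-like fields
with vertical shear and temporally autocorrelated day-to-day noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

#: The full pressure-layer set (mb), surface to ~5.5 km.
STANDARD_LEVELS_MB = (
    1000, 975, 950, 925, 900, 875, 850, 825, 800, 775,
    750, 700, 650, 600, 550, 500,
)

SIX_HOURS = np.timedelta64(6, "h")


def as_utc64(t) -> np.datetime64:
    """Coerce str / datetime / datetime64 / (tz-aware) Timestamp to
    naive-UTC datetime64[s]."""
    import pandas as pd

    ts = pd.Timestamp(t)
    if ts.tz is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts.to_datetime64().astype("datetime64[s]")


class WindFieldFormatError(ValueError):
    """A gridded wind file or array set violates a WindField invariant."""


class OutOfDomainError(KeyError):
    """A point query fell outside the field's spatial or level extent."""


def _validate(times, levels, lats, lons, u, v) -> None:
    times = np.asarray(times, dtype="datetime64[s]")
    if times.size < 1:
        raise WindFieldFormatError("field has no analysis times")
    if times.size > 1:
        dt = np.diff(times)
        if not np.all(dt == SIX_HOURS):
            raise WindFieldFormatError("analysis times are not exactly 6 h apart")
    hours = (times - times.astype("datetime64[D]")) / np.timedelta64(1, "h")
    if not np.all(np.isin(hours, [0.0, 6.0, 12.0, 18.0])):
        raise WindFieldFormatError("analysis times must fall on 0:00/6:00/12:00/18:00 UTC")
    levels = np.asarray(levels, dtype=float)
    if not set(levels).issubset(set(float(x) for x in STANDARD_LEVELS_MB)):
        raise WindFieldFormatError(
            f"levels must be a subset of {STANDARD_LEVELS_MB} mb"
        )
    if levels.size > 1 and not np.all(np.diff(levels) < 0):
        raise WindFieldFormatError("levels must be strictly decreasing")
    for name, ax in (("lat", lats), ("lon", lons)):
        ax = np.asarray(ax, dtype=float)
        if ax.size > 1:
            steps = np.diff(ax)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise WindFieldFormatError(f"{name} grid spacing is not uniform")
    shape = (len(times), len(levels), len(np.atleast_1d(lats)), len(np.atleast_1d(lons)))
    for name, comp in (("u", u), ("v", v)):
        comp = np.asarray(comp, dtype=float)
        if comp.shape != shape:
            raise WindFieldFormatError(
                f"{name} has shape {comp.shape}, expected {shape}"
            )
        if not np.all(np.isfinite(comp)):
            raise WindFieldFormatError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class WindField:
    """Gridded eastward/northward wind (m/s) on time x level x lat x lon.

    Invariants (checked at construction): 6-hourly analysis times on
    0/6/12/18 UTC, strictly decreasing pressure levels drawn from the
    standard 1000-500 mb set, uniform lat/lon spacing, finite components.
    """

    times: np.ndarray   # datetime64[s], ascending, 6-hourly
    levels: np.ndarray  # mb, strictly decreasing
    lats: np.ndarray    # degrees, uniform spacing
    lons: np.ndarray    # degrees, uniform spacing
    u: np.ndarray       # m/s, (time, level, lat, lon)
    v: np.ndarray       # m/s, (time, level, lat, lon)

    def __post_init__(self) -> None:
        _validate(self.times, self.levels, self.lats, self.lons, self.u, self.v)
        object.__setattr__(self, "times", np.asarray(self.times, dtype="datetime64[s]"))
        for name in ("levels", "lats", "lons", "u", "v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "u": (("time", "level", "lat", "lon"), self.u),
                "v": (("time", "level", "lat", "lon"), self.v),
            },
            coords={
                "time": self.times,
                "level": self.levels,
                "lat": self.lats,
                "lon": self.lons,
            },
            attrs={"Conventions": "CF-1.6"},
        )

    def save(self, path) -> None:
        """Write as NetCDF-3 classic (readable by any NetCDF tool)."""
        ds = self.to_dataset()
        ds.to_netcdf(path, engine="scipy")


def load_wind_field(path) -> WindField:
    """Read a gridded wind file into a validated :class:`WindField`.

    The file must carry variables ``u`` and ``v`` on time/level/lat/lon
    axes; any violated WindField invariant raises
    :class:`WindFieldFormatError` naming the problem.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        for var in ("u", "v"):
            if var not in ds:
                raise WindFieldFormatError(f"missing wind component '{var}'")
        for dim in ("time", "level", "lat", "lon"):
            if dim not in ds.dims:
                raise WindFieldFormatError(f"missing dimension '{dim}'")
        ds = ds.transpose("time", "level", "lat", "lon")
        return WindField(
            times=ds["time"].values.astype("datetime64[s]"),
            levels=ds["level"].values,
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            u=ds["u"].values,
            v=ds["v"].values,
        )


def _nearest_index(grid: np.ndarray, value: float, name: str) -> int:
    grid = np.asarray(grid, dtype=float)
    half = 0.5 * (abs(grid[1] - grid[0]) if grid.size > 1 else max(abs(grid[0]), 1.0))
    if value < grid.min() - half or value > grid.max() + half:
        raise OutOfDomainError(f"{name}={value} outside field extent [{grid.min()}, {grid.max()}]")
    return int(np.argmin(np.abs(grid - value)))


def sample_wind(field: WindField, lat: float, lon: float, level: float, t) -> tuple[float, float]:
    """(u, v) at the nearest grid cell and nearest analysis time.

    Nearest-neighbour in lat/lon/level; the nearest 6-hourly analysis time
    in t, with exact ties broken toward the earlier analysis.  Queries
    outside the spatial/level extent raise :class:`OutOfDomainError`.
    """
    i_lat = _nearest_index(field.lats, lat, "lat")
    i_lon = _nearest_index(field.lons, lon, "lon")
    levels = field.levels
    if not (min(levels) - 12.5 <= level <= max(levels) + 12.5):
        raise OutOfDomainError(f"level={level} outside field levels")
    i_lev = int(np.argmin(np.abs(levels - level)))
    t64 = as_utc64(t)
    # |dt| minimised; np.argmin returns the first (earlier) index on ties.
    dt = np.abs((field.times - t64) / np.timedelta64(1, "s"))
    i_t = int(np.argmin(dt))
    return float(field.u[i_t, i_lev, i_lat, i_lon]), float(field.v[i_t, i_lev, i_lat, i_lon])


@dataclass(frozen=True)
class SyntheticWindConfig:
    """Parameters of a synthetic trade-wind field.

    ``mean_trade_u``/``mean_trade_v`` are the prevailing mean components in
    m/s (a NE trade blows toward the SW: both negative).  ``shear_profile``
    multiplies the means per pressure level (strongest aloft in the
    defaults).  ``temporal_sd`` scales AR(1) day-to-day noise shared across
    the grid; ``seasonal_reversal`` rescales the trade means (-1 turns
    the trades around) for a
    reversed-season scenario.  A fixed seed reproduces the field exactly.
    """

    mean_trade_u: float = -3.5
    mean_trade_v: float = -3.5
    shear_profile: tuple[float, ...] = (1.0, 1.2, 1.4, 1.6)
    temporal_sd: float = 2.0
    temporal_autocorr: float = 0.8
    seasonal_reversal: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temporal_sd < 0:
            raise ValueError("temporal_sd must be >= 0")
        if not 0 <= self.temporal_autocorr < 1:
            raise ValueError("temporal_autocorr must be in [0, 1)")


def generate_synthetic_wind(
    cfg: SyntheticWindConfig,
    extent: tuple[float, float, float, float],
    times,
    levels=(925, 850, 750, 650),
    resolution: float = 0.4,
) -> WindField:
    """Synthesize a trade-wind field over ``extent`` = (lat0, lat1, lon0, lon1).

    field(t, l, y, x) = mean * shear(l) * seasonal + AR(1) noise(t, l)
    with noise scale ``temporal_sd``; deterministic under a fixed seed and
    unbiased for the configured means in expectation.
    """
    lat0, lat1, lon0, lon1 = extent
    lats = np.round(np.arange(lat0, lat1 + resolution / 2, resolution), 6)
    lons = np.round(np.arange(lon0, lon1 + resolution / 2, resolution), 6)
    levels = np.asarray(sorted(levels, reverse=True), dtype=float)
    if len(cfg.shear_profile) != len(levels):
        raise ValueError(
            f"shear_profile has {len(cfg.shear_profile)} entries for {len(levels)} levels"
        )
    times = np.asarray(times, dtype="datetime64[s]")
    nt, nl, ny, nx = len(times), len(levels), len(lats), len(lons)

    rng = np.random.default_rng(cfg.seed)
    phi = cfg.temporal_autocorr
    innov_sd = cfg.temporal_sd * np.sqrt(1 - phi**2)
    # AR(1) per level and component, shared across the spatial grid so that
    # the noise behaves like a synoptic-scale (grid-coherent) anomaly.
    noise = np.zeros((2, nt, nl))
    if cfg.temporal_sd > 0:
        noise[:, 0, :] = rng.normal(0.0, cfg.temporal_sd, size=(2, nl))
        eps = rng.normal(0.0, innov_sd, size=(2, nt, nl))
        for t in range(1, nt):
            noise[:, t, :] = phi * noise[:, t - 1, :] + eps[:, t, :]

    shear = np.asarray(cfg.shear_profile, dtype=float)  # aligned with descending levels
    base_u = cfg.mean_trade_u * cfg.seasonal_reversal * shear
    base_v = cfg.mean_trade_v * cfg.seasonal_reversal * shear
    u = (base_u[None, :] + noise[0])[:, :, None, None] * np.ones((nt, nl, ny, nx))
    v = (base_v[None, :] + noise[1])[:, :, None, None] * np.ones((nt, nl, ny, nx))
    return WindField(times=times, levels=levels, lats=lats, lons=lons, u=u, v=v)


def analysis_times(start, n: int) -> np.ndarray:
    """n consecutive 6-hourly analysis times from the first analysis >= start."""
    t0 = as_utc64(start)
    day = t0.astype("datetime64[D]").astype("datetime64[s]")
    offset_h = float((t0 - day) / np.timedelta64(1, "h"))
    first = day + np.timedelta64(int(np.ceil(offset_h / 6.0) * 6 * 3600), "s")
    return first + np.arange(n) * SIX_HOURS
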