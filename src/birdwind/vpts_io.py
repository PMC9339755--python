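"""Readers and writers for vertical-profile time series (VPTS), gridded wind
fields, and weather-radar site metadata.

The on-disk conventions follow the vertical-profile CSV dialect of the
vol2bird ecosystem: comma-separated UTF-8 with ISO-8601 UTC timestamps
(trailing ``Z``) and columns ``radar, datetime, height, dens, u, v, sd_vvp``.
``height`` is the 200-m altitude-bin center in meters above mean sea level;
``dens`` is bird density in birds/km^3; ``u``/``v`` are the eastward/northward
ground-velocity components in m/s; ``sd_vvp`` is the radial-velocity standard
deviation in m/s (empty field = missing, never zero-filled).

Wind grids are 4-D (time x latitude x longitude x pressure level) eastward/
northward wind components, NetCDF on disk (CF-style named dimensions) with a
long-format CSV fallback (``time,lat,lon,level,U,V``) for dependency-free
fixtures.

Parsers never silently coerce: every dropped row is counted in a reported
skip tally, and malformed values raise or are collected as row-level errors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

#: Exact VPTS CSV column names, in order.
VPTS_COLUMNS = ("radar", "datetime", "height", "dens", "u", "v", "sd_vvp")

#: Default altitude-bin lattice: centers at 100 + 200*k m, below 5000 m.
BIN_CENTER0 = 100.0
BIN_WIDTH = 200.0
MAX_ALTITUDE = 5000.0


class VptsFormatError(ValueError):
    """A VPTS, wind-grid, or metadata file violates its documented format."""


@dataclass(frozen=True)
class RadarMetadata:
    """Identity and position of one weather radar.

    Parameters
    ----------
    radar_id : str
        Short unique token, e.g. ``"frabb"``.
    latitude, longitude : float
        Site coordinates in decimal degrees (north / east positive).
    antenna_altitude : float
        Antenna altitude in meters above mean sea level.
    """

    radar_id: str
    latitude: float
    longitude: float
    antenna_altitude: float = 0.0

    def __post_init__(self) -> None:
        if not self.radar_id:
            raise ValueError("radar_id must be a non-empty token")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(
                f"radar {self.radar_id!r}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(
                f"radar {self.radar_id!r}: longitude {self.longitude} outside [-180, 180]"
            )


@dataclass
class WindGrid:
    """Gridded eastward (U) and northward (V) wind on a regular 4-D grid.

    Axes are ``times`` (ascending UTC instants), ``latitudes`` and
    ``longitudes`` (ascending degrees), and ``pressure_levels`` (descending
    hPa, e.g. 1000 ... 550).  ``U`` and ``V`` have shape
    ``(n_time, n_lat, n_lon, n_level)`` in m/s and are finite everywhere.
    """

    times: np.ndarray
    latitudes: np.ndarray
    longitudes: np.ndarray
    pressure_levels: np.ndarray
    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        self.pressure_levels = np.asarray(self.pressure_levels, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        for name, ax, ascending in (
            ("times", self.times.astype("int64"), True),
            ("latitudes", self.latitudes, True),
            ("longitudes", self.longitudes, True),
            ("pressure_levels", self.pressure_levels, False),
        ):
            d = np.diff(ax.astype(float))
            ok = np.all(d > 0) if ascending else np.all(d < 0)
            if len(ax) and not ok:
                order = "ascending" if ascending else "descending"
                raise VptsFormatError(f"wind grid axis {name!r} is not strictly {order}")
        shape = (
            len(self.times),
            len(self.latitudes),
            len(self.longitudes),
            len(self.pressure_levels),
        )
        for name, arr in (("U", self.U), ("V", self.V)):
            if arr.shape != shape:
                raise VptsFormatError(
                    f"wind grid variable {name} has shape {arr.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise VptsFormatError(f"wind grid variable {name} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.U.shape

    def to_dataset(self) -> xr.Dataset:
        """Represent the grid as an xarray Dataset with CF-style dimensions."""
        return xr.Dataset(
            {
                "U": (("time", "latitude", "longitude", "level"), self.U),
                "V": (("time", "latitude", "longitude", "level"), self.V),
            },
            coords={
                "time": self.times,
                "latitude": self.latitudes,
                "longitude": self.longitudes,
                "level": self.pressure_levels,
            },
        )


@dataclass
class VptsReadResult:
    """Outcome of :func:`read_vpts`: parsed records plus the skip tally."""

    records: pd.DataFrame
    n_skipped: int = 0
    row_errors: list[str] = field(default_factory=list)


def _validate_records(records: pd.DataFrame, cadence: str | pd.Timedelta) -> None:
    """Enforce the profile-record invariants on a parsed frame."""
    if len(records) == 0:
        return
    heights = records["height"].to_numpy(dtype=float)
    on_lattice = (
        (np.abs((heights - BIN_CENTER0) % BIN_WIDTH) < 1e-6)
        | (np.abs((heights - BIN_CENTER0) % BIN_WIDTH - BIN_WIDTH) < 1e-6)
    ) & (heights >= BIN_CENTER0 - 1e-6) & (heights < MAX_ALTITUDE)
    if not np.all(on_lattice):
        bad = sorted(set(heights[~on_lattice]))[:5]
        raise VptsFormatError(
            f"heights off the {BIN_CENTER0:g}+{BIN_WIDTH:g}k lattice below "
            f"{MAX_ALTITUDE:g} m: {bad}"
        )
    cadence = pd.Timedelta(cadence)
    ts = pd.DatetimeIndex(records["datetime"])
    misaligned = (ts - ts.normalize()) % cadence != pd.Timedelta(0)
    if misaligned.any():
        bad = ts[misaligned][:3].tolist()
        raise VptsFormatError(f"timestamps not aligned to cadence {cadence}: {bad}")


def read_vpts(path: str | Path, cadence: str | pd.Timedelta = "5min") -> VptsReadResult:
    """Read a VPTS CSV file into a validated record table.

    Rows with missing ``u`` or ``v`` are dropped and counted in
    ``n_skipped``; rows with negative density are rejected and reported in
    ``row_errors`` (and likewise dropped).  Unknown or missing columns are
    fatal.

    Parameters
    ----------
    path : path-like
        CSV file with header ``radar,datetime,height,dens,u,v,sd_vvp``.
    cadence : str or Timedelta
        Declared temporal resolution; timestamps must align to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VPTS file not found: {path}")
    df = pd.read_csv(path, dtype={"radar": str}, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in VPTS_COLUMNS]
    if unknown:
        raise VptsFormatError(f"unknown VPTS column(s): {unknown}")
    missing = [c for c in VPTS_COLUMNS if c not in df.columns]
    if missing:
        raise VptsFormatError(f"missing VPTS column(s): {missing}")
    df = df[list(VPTS_COLUMNS)]
    df["datetime"] = pd.to_datetime(df["datetime"], utc=True).dt.tz_localize(None)
    for col in ("height", "dens", "u", "v", "sd_vvp"):
        df[col] = pd.to_numeric(df[col], errors="raise")

    n_before = len(df)
    keep = df["u"].notna() & df["v"].notna()
    n_skipped = int(n_before - keep.sum())
    df = df[keep]

    row_errors: list[str] = []
    neg = df["dens"] < 0
    if neg.any():
        for idx in df.index[neg]:
            row_errors.append(
                f"row {idx}: negative density {df.at[idx, 'dens']} "
                f"({df.at[idx, 'radar']} @ {df.at[idx, 'datetime']})"
            )
        df = df[~neg]
    df = df.reset_index(drop=True)
    _validate_records(df, cadence)
    return VptsReadResult(records=df, n_skipped=n_skipped, row_errors=row_errors)


def write_vpts(records: pd.DataFrame, path: str | Path) -> None:
    """Write records to VPTS CSV with deterministic column and row order.

    Rows are sorted by (radar, datetime, height); floats are printed with 17
    significant digits so ``read_vpts(write_vpts(x))`` is bit-faithful.
    """
    missing = [c for c in VPTS_COLUMNS if c not in records.columns]
    if missing:
        raise VptsFormatError(f"records missing column(s): {missing}")
    out = records[list(VPTS_COLUMNS)].sort_values(
        ["radar", "datetime", "height"], kind="mergesort"
    )
    out = out.copy()
    out["datetime"] = pd.DatetimeIndex(out["datetime"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.17g")


def read_radar_metadata(path: str | Path) -> list[RadarMetadata]:
    """Read radar site metadata from CSV.

    Requires columns ``radar_id, latitude, longitude, antenna_altitude``;
    duplicate ids and out-of-range coordinates are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"radar metadata file not found: {path}")
    df = pd.read_csv(path, dtype={"radar_id": str})
    required = ["radar_id", "latitude", "longitude", "antenna_altitude"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VptsFormatError(f"radar metadata missing column(s): {missing}")
    dup = df["radar_id"][df["radar_id"].duplicated()]
    if len(dup):
        raise VptsFormatError(f"duplicate radar_id(s): {sorted(set(dup))}")
    return [
        RadarMetadata(
            radar_id=row.radar_id,
            latitude=float(row.latitude),
            longitude=float(row.longitude),
            antenna_altitude=float(row.antenna_altitude),
        )
        for row in df.itertuples()
    ]


def write_radar_metadata(radars: Iterable[RadarMetadata], path: str | Path) -> None:
    """Write radar site metadata to CSV (columns fixed, row order by id)."""
    rows = [dataclasses.asdict(r) for r in sorted(radars, key=lambda r: r.radar_id)]
    pd.DataFrame(
        rows, columns=["radar_id", "latitude", "longitude", "antenna_altitude"]
    ).sort_values("radar_id").to_csv(path, index=False, float_format="%.17g")


_DIM_ALIASES = {
    "time": "time",
    "latitude": "latitude",
    "lat": "latitude",
    "longitude": "longitude",
    "lon": "longitude",
    "level": "level",
    "pressure_level": "level",
    "plev": "level",
}
_VAR_ALIASES = {"U": "U", "u": "U", "V": "V", "v": "V"}


def _grid_from_dataset(ds: xr.Dataset) -> WindGrid:
    rename = {d: _DIM_ALIASES[d] for d in ds.dims if d in _DIM_ALIASES}
    ds = ds.rename(rename)
    for dim in ("time", "latitude", "longitude", "level"):
        if dim not in ds.dims:
            raise VptsFormatError(f"wind grid file lacks dimension {dim!r}")
    var_map = {v: _VAR_ALIASES[str(v)] for v in ds.data_vars if str(v) in _VAR_ALIASES}
    ds = ds.rename(var_map)
    for var in ("U", "V"):
        if var not in ds.data_vars:
            raise VptsFormatError(f"wind grid file lacks variable {var!r}")
    # normalize orientation: time/lat/lon ascending, pressure descending
    ds = ds.sortby("time").sortby("latitude").sortby("longitude")
    ds = ds.sortby("level", ascending=False)
    ds = ds.transpose("time", "latitude", "longitude", "level")
    return WindGrid(
        times=ds["time"].values,
        latitudes=ds["latitude"].values,
        longitudes=ds["longitude"].values,
        pressure_levels=ds["level"].values,
        U=ds["U"].values,
        V=ds["V"].values,
    )


def read_wind_grid(path: str | Path) -> WindGrid:
    """Read a 4-D wind grid from NetCDF (or the long-format CSV fallback).

    The returned grid is normalized to axis order (time, lat, lon, level)
    with time/lat/lon ascending and pressure levels descending, regardless of
    on-disk orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"wind grid file not found: {path}")
    if path.suffix.lower() == ".csv":
        return _read_wind_grid_csv(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        return _grid_from_dataset(ds.load())


def _read_wind_grid_csv(path: Path) -> WindGrid:
    df = pd.read_csv(path)
    required = ["time", "lat", "lon", "level", "U", "V"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VptsFormatError(f"wind grid CSV missing column(s): {missing}")
    df["time"] = pd.to_datetime(df["time"], utc=True).dt.tz_localize(None)
    ds = df.set_index(["time", "lat", "lon", "level"])[["U", "V"]].to_xarray()
    if ds["U"].isnull().any() or ds["V"].isnull().any():
        raise VptsFormatError("wind grid CSV is not a complete grid (missing cells)")
    return _grid_from_dataset(ds.rename({"lat": "latitude", "lon": "longitude"}))


def write_wind_grid(grid: WindGrid, path: str | Path) -> None:
    """Write a wind grid to NetCDF (``.nc``) or long-format CSV (``.csv``)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = (
            grid.to_dataset()
            .to_dataframe()
            .reset_index()
            .rename(columns={"latitude": "lat", "longitude": "lon"})
        )
        df["time"] = pd.DatetimeIndex(df["time"]).strftime("%Y-%m-%dT%H:%M:%SZ")
        df[["time", "lat", "lon", "level", "U", "V"]].to_csv(
            path, index=False, float_format="%.17g"
        )
    else:
        grid.to_dataset().to_netcdf(path, engine="scipy")


def radars_by_id(radars: Sequence[RadarMetadata]) -> dict[str, RadarMetadata]:
    """Index radar metadata by id, rejecting duplicates."""
    out: dict[str, RadarMetadata] = {}
    for r in radars:
        if r.radar_id in out:
            raise VptsFormatError(f"duplicate radar_id: {r.radar_id}")
        out[r.radar_id] = r
    return out
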