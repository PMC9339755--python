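"""Attach reanalysis wind to radar profile records.

The wind grid is native in pressure coordinates while radar altitude bins
are in meters, so a query altitude is first mapped to pressure with the
International Standard Atmosphere (ISA, troposphere branch) and the wind is
then interpolated multilinearly over the 2^4 surrounding grid nodes in
(time, latitude, longitude, pressure) space.  There is no extrapolation,
ever: a query outside any axis range is an error (point queries) or a
counted drop (bulk attachment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .vpts_io import RadarMetadata, WindGrid, radars_by_id

# ISA constants (troposphere branch)
P0_HPA = 1013.25  # sea-level standard pressure
T0_K = 288.15  # sea-level standard temperature
LAPSE_K_PER_M = 0.0065
R_GAS = 8.3144598  # J/(mol K)
G0 = 9.80665  # m/s^2
M_AIR = 0.0289644  # kg/mol
_EXP = R_GAS * LAPSE_K_PER_M / (G0 * M_AIR)  # ~0.19026


class CoverageError(ValueError):
    """A wind query lies outside the grid's space-time-pressure coverage."""


@dataclass(frozen=True)
class WindSample:
    """Interpolated eastward (U) and northward (V) wind, m/s."""

    U: float
    V: float


def pressure_to_altitude(p_hpa):
    """ISA altitude (m above mean sea level) for pressure ``p_hpa``.

    z = (T0/L) * (1 - (p/p0)^(R*L/(g*M))); strictly decreasing in p.
    Valid for 0 < p <= 1013.25 hPa.
    """
    p = np.asarray(p_hpa, dtype=float)
    if np.any(p <= 0) or np.any(p > P0_HPA):
        raise ValueError(f"pressure outside (0, {P0_HPA}] hPa: {p_hpa}")
    z = (T0_K / LAPSE_K_PER_M) * (1.0 - (p / P0_HPA) ** _EXP)
    return z if z.shape else float(z)


def altitude_to_pressure(z_m):
    """Inverse ISA mapping: pressure (hPa) at altitude ``z_m`` (0–11000 m)."""
    z = np.asarray(z_m, dtype=float)
    if np.any(z < 0) or np.any(z > 11000.0):
        raise ValueError(f"altitude outside [0, 11000] m: {z_m}")
    p = P0_HPA * (1.0 - z * LAPSE_K_PER_M / T0_K) ** (1.0 / _EXP)
    return p if p.shape else float(p)


def _times_to_float(times) -> np.ndarray:
    return pd.DatetimeIndex(times).asi8.astype(float) / 1e9  # seconds


class WindInterpolator:
    """Multilinear 4-D interpolator over a :class:`WindGrid`.

    Interpolation is linear along each of (time, lat, lon, pressure) and
    exact at grid nodes; the result is a convex combination of the 16
    surrounding node values.
    """

    def __init__(self, grid: WindGrid):
        self.grid = grid
        t = _times_to_float(grid.times)
        # pressure axis is stored descending; flip to ascending for scipy
        p = grid.pressure_levels[::-1]
        axes = (t, grid.latitudes, grid.longitudes, p)
        uv = np.stack([grid.U[..., ::-1], grid.V[..., ::-1]], axis=-1)
        self._rgi = RegularGridInterpolator(
            axes, uv, method="linear", bounds_error=False, fill_value=np.nan
        )
        self._bounds = [(ax.min(), ax.max()) for ax in axes]

    def query(self, times, lats, lons, alts_m) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate (U, V) at points; NaN where out of coverage."""
        t = _times_to_float(times)
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        z = np.asarray(alts_m, dtype=float)
        with np.errstate(invalid="ignore"):
            p = np.where(
                (z >= 0) & (z <= 11000.0),
                P0_HPA * (1.0 - z * LAPSE_K_PER_M / T0_K) ** (1.0 / _EXP),
                np.nan,
            )
        pts = np.column_stack(np.broadcast_arrays(t, lats, lons, p))
        out = self._rgi(pts)
        return out[:, 0], out[:, 1]


def interpolate_wind(grid: WindGrid, t, lat: float, lon: float, z_m: float) -> WindSample:
    """Interpolate wind at a single space-time-altitude point.

    Raises :class:`CoverageError` if the point (after mapping altitude to
    ISA pressure) falls outside the grid along any axis.
    """
    interp = grid if isinstance(grid, WindInterpolator) else WindInterpolator(grid)
    U, V = interp.query([t], [lat], [lon], [z_m])
    if not (np.isfinite(U[0]) and np.isfinite(V[0])):
        raise CoverageError(
            f"query (t={t}, lat={lat}, lon={lon}, z={z_m} m) outside wind-grid coverage"
        )
    return WindSample(U=float(U[0]), V=float(V[0]))


@dataclass
class AttachResult:
    """Records with wind columns attached, plus the out-of-coverage tally."""

    records: pd.DataFrame
    n_dropped: int


def attach_wind(
    records: pd.DataFrame,
    grid: WindGrid,
    radars: list[RadarMetadata] | dict[str, RadarMetadata],
) -> AttachResult:
    """Attach interpolated (U, V) to every profile record.

    Wind is interpolated at (timestamp, radar latitude, radar longitude,
    record altitude).  Records out of grid coverage are dropped and counted;
    an unknown ``radar`` id is fatal.
    """
    by_id = radars if isinstance(radars, dict) else radars_by_id(radars)
    unknown = set(records["radar"]) - set(by_id)
    if unknown:
        raise KeyError(f"records reference unknown radar_id(s): {sorted(unknown)}")
    lats = records["radar"].map(lambda r: by_id[r].latitude).to_numpy(dtype=float)
    lons = records["radar"].map(lambda r: by_id[r].longitude).to_numpy(dtype=float)
    interp = WindInterpolator(grid)
    U, V = interp.query(records["datetime"], lats, lons, records["height"].to_numpy(dtype=float))
    ok = np.isfinite(U) & np.isfinite(V)
    out = records.copy()
    out["U"] = U
    out["V"] = V
    attached = out[ok].reset_index(drop=True)
    return AttachResult(records=attached, n_dropped=int((~ok).sum()))
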