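"""Velocity-triangle decomposition and weighted statistics.

A migrating bird's ground velocity (u, v) is the vector sum of its air
velocity and the wind (U, V).  Ground speed and airspeed are

    Vg = sqrt(u^2 + v^2),      Va = sqrt((u - U)^2 + (v - V)^2),

so airspeed is computed locally per record from the wind at that exact
place, time and altitude.  Wind profit is the signed projection of the wind
vector onto the preferred migration direction alpha (45 deg toward NE in
spring, 225 deg toward SW in autumn):

    wp = U*sin(alpha) + V*cos(alpha).

Compass convention throughout: degrees clockwise from geographic north,
"toward" semantics for both bird track and wind.  Averages over birds are
weighted by bird density ("experienced" statistics); unweighted averages
describe what was available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Preferred migration directions, compass degrees toward which birds fly.
ALPHA_SPRING = 45.0
ALPHA_AUTUMN = 225.0


def _check_finite(name: str, *arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError(f"{name}: non-finite input")


def ground_speed(u, v):
    """Ground speed Vg = sqrt(u^2 + v^2), m/s."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_finite("ground_speed", u, v)
    out = np.hypot(u, v)
    return out if out.shape else float(out)


def airspeed(u, v, U, V):
    """Airspeed Va = sqrt((u-U)^2 + (v-V)^2), m/s."""
    u, v, U, V = (np.asarray(x, dtype=float) for x in (u, v, U, V))
    _check_finite("airspeed", u, v, U, V)
    out = np.hypot(u - U, v - V)
    return out if out.shape else float(out)


def bearing(x_east, y_north):
    """Compass bearing (degrees clockwise from north) a vector points toward.

    Undefined for the zero vector (raises for scalar input; NaN elementwise
    for array input).
    """
    x = np.asarray(x_east, dtype=float)
    y = np.asarray(y_north, dtype=float)
    zero = (x == 0) & (y == 0)
    if x.shape == () and zero:
        raise ValueError("undefined bearing: zero vector")
    out = np.degrees(np.arctan2(x, y)) % 360.0
    out = np.where(zero, np.nan, out)
    return out if out.shape else float(out)


def wind_profit(U, V, alpha):
    """Signed projection of the wind on preferred direction ``alpha`` (deg).

    Equals +|wind| when the wind blows exactly toward alpha and -|wind| when
    exactly opposite.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    a = np.radians(np.asarray(alpha, dtype=float))
    out = U * np.sin(a) + V * np.cos(a)
    return out if out.shape else float(out)


def decompose(
    records: pd.DataFrame,
    season_cutoff: str = "07-15",
    alpha_spring: float = ALPHA_SPRING,
    alpha_autumn: float = ALPHA_AUTUMN,
) -> pd.DataFrame:
    """Velocity-triangle decomposition of wind-attached profile records.

    Input columns: the VPTS columns plus attached wind ``U``, ``V``.
    Returns a copy with added columns ``Vg``, ``Va``, ``W`` (wind speed),
    ``track_bearing``, ``wind_bearing``, ``wp`` (wind profit toward the
    seasonal preferred direction), ``season`` and ``alpha``.
    """
    from .aggregate import assign_season  # deferred: aggregate builds on this module

    out = records.copy()
    u = out["u"].to_numpy(dtype=float)
    v = out["v"].to_numpy(dtype=float)
    U = out["U"].to_numpy(dtype=float)
    V = out["V"].to_numpy(dtype=float)
    _check_finite("decompose", u, v, U, V)
    out["Vg"] = np.hypot(u, v)
    out["Va"] = np.hypot(u - U, v - V)
    out["W"] = np.hypot(U, V)
    out["track_bearing"] = bearing(u, v) if len(out) else np.empty(0)
    out["wind_bearing"] = bearing(U, V) if len(out) else np.empty(0)
    season = assign_season(out["datetime"], cutoff=season_cutoff)
    out["season"] = season
    out["alpha"] = np.where(season == "spring", alpha_spring, alpha_autumn)
    out["wp"] = wind_profit(U, V, out["alpha"].to_numpy())
    return out


@dataclass(frozen=True)
class WeightedStats:
    """Weighted mean / population SD of a scalar quantity."""

    mean: float
    sd: float
    total_weight: float
    n: int


def weighted_stats(values, weights) -> WeightedStats:
    """Density-weighted mean and population SD.

    mean = sum(w*x)/sum(w); sd = sqrt(sum(w*(x-mean)^2)/sum(w)).
    Weights must be non-negative with positive total.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("negative weight")
    tw = w.sum()
    if not tw > 0:
        raise ValueError("total weight must be positive")
    mean = float(np.dot(w, x) / tw)
    sd = float(np.sqrt(np.dot(w, (x - mean) ** 2) / tw))
    return WeightedStats(mean=mean, sd=sd, total_weight=float(tw), n=int(x.size))


@dataclass(frozen=True)
class VectorAverage:
    """Weighted mean velocity vector with its magnitude and bearing."""

    u_mean: float
    v_mean: float
    magnitude: float
    bearing: float  # NaN for a zero mean vector


def vectorial_average(u_list, v_list, weights) -> VectorAverage:
    """Density-weighted vector mean of velocities.

    The magnitude of the mean vector is at most the weighted mean of the
    individual magnitudes, with equality only when all directions agree —
    scattered directions shrink the vectorial average.
    """
    su = weighted_stats(u_list, weights)
    sv = weighted_stats(v_list, weights)
    um, vm = su.mean, sv.mean
    mag = float(np.hypot(um, vm))
    brg = float("nan") if mag == 0.0 else float(bearing(um, vm))
    return VectorAverage(u_mean=um, v_mean=vm, magnitude=mag, bearing=brg)
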