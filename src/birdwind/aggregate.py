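"""Aggregation of per-record kinematics to the four observation scales:
seasonal split, nightly time series (with smoothing and within-season
trends), per-radar spatial averages, and altitudinal profiles — plus the
experienced-vs-available wind contrast.

Nightly series use scalar density-weighted means pooled over all radars and
altitudes; spatial maps and altitude profiles use density-weighted
*vectorial* averages (the mean velocity vector), which shrink when
directions scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import solar
from .kinematics import WeightedStats, vectorial_average, weighted_stats
from .vpts_io import RadarMetadata, radars_by_id

#: Days per month used to express trend slopes in m/s per month.
DAYS_PER_MONTH = 30.44

SEASON_CUTOFF = "07-15"


def _parse_cutoff(cutoff: str) -> tuple[int, int]:
    month, day = cutoff.split("-")
    return int(month), int(day)


def assign_season(timestamps, cutoff: str = SEASON_CUTOFF):
    """Label timestamps ``"spring"`` or ``"autumn"`` by a month-day cutoff.

    Strictly before the cutoff day (default July 15) is spring; the cutoff
    day itself and everything after is autumn.
    """
    ts = pd.DatetimeIndex(timestamps)
    cm, cd = _parse_cutoff(cutoff)
    month = ts.month.to_numpy()
    day = ts.day.to_numpy()
    spring = (month < cm) | ((month == cm) & (day < cd))
    out = np.where(spring, "spring", "autumn")
    return out if isinstance(timestamps, (pd.Series, pd.DatetimeIndex, np.ndarray, list)) else str(out)


def assign_night(timestamps, radar: RadarMetadata):
    """Night id (civil date of the evening the night starts) per timestamp.

    Returns ``(night_id, is_night)``: daytime records (solar elevation >= 0
    at the radar) get ``NaT`` and ``is_night=False`` and should be excluded
    by the caller, who keeps the tally.
    """
    night = solar.is_night(timestamps, radar.latitude, radar.longitude)
    nid = solar.night_date(timestamps, radar.longitude)
    nid = np.where(night, nid, np.datetime64("NaT"))
    return nid, night


@dataclass
class NightAssignment:
    """Records with a ``night_id`` column, plus the daytime-exclusion tally."""

    records: pd.DataFrame
    n_excluded: int


def add_night_ids(
    records: pd.DataFrame, radars: list[RadarMetadata] | dict[str, RadarMetadata]
) -> NightAssignment:
    """Attach night ids to records of many radars, excluding daytime rows."""
    by_id = radars if isinstance(radars, dict) else radars_by_id(radars)
    unknown = set(records["radar"]) - set(by_id)
    if unknown:
        raise KeyError(f"records reference unknown radar_id(s): {sorted(unknown)}")
    out = records.copy()
    nid = np.full(len(out), np.datetime64("NaT"), dtype="datetime64[ns]")
    keep = np.zeros(len(out), dtype=bool)
    for rid, idx in out.groupby("radar", sort=False).indices.items():
        ids, night = assign_night(out["datetime"].iloc[idx], by_id[rid])
        nid[idx] = ids
        keep[idx] = night
    out["night_id"] = nid
    excluded = int((~keep).sum())
    return NightAssignment(records=out[keep].reset_index(drop=True), n_excluded=excluded)


_NIGHTLY_QUANTITIES = ("Vg", "Va", "W", "wp")


def nightly_series(records: pd.DataFrame) -> pd.DataFrame:
    """Per-night density-weighted means pooled across radars and altitudes.

    Input must carry ``night_id`` (see :func:`add_night_ids`) and the
    kinematics columns.  Nights with zero total density are omitted.
    Returns a frame indexed by ``night_id`` with columns Vg, Va, W, wp,
    ``total_density`` and ``n_records``.
    """
    if len(records) == 0:
        raise ValueError("nightly_series: no records")
    w = records["dens"].to_numpy(dtype=float)
    weighted = records[["night_id"]].copy()
    for q in _NIGHTLY_QUANTITIES:
        weighted[q] = records[q].to_numpy(dtype=float) * w
    weighted["dens"] = w
    g = weighted.groupby("night_id", sort=True)
    sums = g.sum()
    total = sums["dens"]
    out = sums[list(_NIGHTLY_QUANTITIES)].div(total, axis=0)
    out["total_density"] = total
    out["n_records"] = g.size()
    out = out[out["total_density"] > 0]
    out.index.name = "night_id"
    return out


def moving_average(series: pd.Series, window: int = 7) -> pd.Series:
    """Centered moving average over calendar nights.

    ``window`` must be odd; at the edges (and across missing nights) the
    window shrinks to the available neighbors — missing nights are skipped,
    never zero-filled.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    idx = pd.DatetimeIndex(series.index)
    full = pd.date_range(idx.min(), idx.max(), freq="D")
    dense = series.reindex(full)
    smoothed = dense.rolling(window, center=True, min_periods=1).mean()
    out = smoothed.loc[idx]
    out.index = series.index
    return out


@dataclass(frozen=True)
class TrendEstimate:
    """Weighted linear trend of a nightly quantity, m/s per month."""

    slope: float
    ci_low: float
    ci_high: float
    n_nights: int


def monthly_trend(
    nightly: pd.DataFrame,
    quantity: str,
    season: str | None = None,
    cutoff: str = SEASON_CUTOFF,
) -> TrendEstimate:
    """Within-season linear trend of a nightly mean, in m/s per month.

    Fits nightly mean vs time (months of 30.44 days) by least squares
    weighted by nightly total density; the 95% CI is the weighted
    least-squares t-interval on the slope.
    """
    df = nightly
    if season is not None:
        seasons = assign_season(df.index, cutoff=cutoff)
        df = df[seasons == season]
    if len(df) < 3:
        raise ValueError(f"monthly_trend: need >= 3 nights, got {len(df)}")
    t_days = (pd.DatetimeIndex(df.index) - pd.DatetimeIndex(df.index).min()) / pd.Timedelta(days=1)
    t_months = np.asarray(t_days, dtype=float) / DAYS_PER_MONTH
    y = df[quantity].to_numpy(dtype=float)
    w = df["total_density"].to_numpy(dtype=float)
    X = sm.add_constant(t_months)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero residual variance on exact fits
        res = sm.WLS(y, X, weights=w).fit()
        ci = res.conf_int(alpha=0.05)
    return TrendEstimate(
        slope=float(res.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        n_nights=int(len(df)),
    )


def _vector_block(prefix: str, ue, ve, w) -> dict[str, float]:
    va = vectorial_average(ue, ve, w)
    return {
        f"{prefix}_u": va.u_mean,
        f"{prefix}_v": va.v_mean,
        f"{prefix}_speed": va.magnitude,
        f"{prefix}_bearing": va.bearing,
    }


def _weighted_mean_or_nan(x: np.ndarray, w: np.ndarray) -> float:
    ok = np.isfinite(x) & (w > 0)
    if not ok.any() or w[ok].sum() <= 0:
        return float("nan")
    return float(np.dot(w[ok], x[ok]) / w[ok].sum())


def altitude_profile(records: pd.DataFrame, season: str | None = None) -> pd.DataFrame:
    """Per (season, altitude bin) vertical profile of the three vector fields.

    For every 200-m bin: density-weighted vectorial averages of the ground,
    air and wind vectors (magnitude + bearing), scalar weighted means of
    Vg/Va/W, the weighted mean sd_vvp, and the summed density.
    """
    if len(records) == 0:
        raise ValueError("altitude_profile: no records")
    df = records if season is None else records[records["season"] == season]
    rows = []
    for (seas, height), sub in df.groupby(["season", "height"], sort=True):
        w = sub["dens"].to_numpy(dtype=float)
        if w.sum() <= 0:
            continue
        u = sub["u"].to_numpy(dtype=float)
        v = sub["v"].to_numpy(dtype=float)
        U = sub["U"].to_numpy(dtype=float)
        V = sub["V"].to_numpy(dtype=float)
        row = {"season": seas, "height": float(height)}
        row.update(_vector_block("ground", u, v, w))
        row.update(_vector_block("air", u - U, v - V, w))
        row.update(_vector_block("wind", U, V, w))
        for q in ("Vg", "Va", "W"):
            row[f"{q}_mean"] = _weighted_mean_or_nan(sub[q].to_numpy(dtype=float), w)
        row["sd_vvp_mean"] = _weighted_mean_or_nan(sub["sd_vvp"].to_numpy(dtype=float), w)
        row["total_density"] = float(w.sum())
        row["n_records"] = int(len(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def default_periods(year: int) -> list[tuple[str, str, str]]:
    """Four three-month periods of the migration year (half-open dates)."""
    return [
        ("Feb-Apr", f"{year}-02-01", f"{year}-05-01"),
        ("May-Jul", f"{year}-05-01", f"{year}-08-01"),
        ("Aug-Oct", f"{year}-08-01", f"{year}-11-01"),
        ("Nov-Jan", f"{year}-11-01", f"{year + 1}-02-01"),
    ]


def spatial_summary(
    records: pd.DataFrame, periods: list[tuple[str, str, str]]
) -> pd.DataFrame:
    """Per (radar, period) density-weighted vectorial averages.

    ``periods`` is a list of ``(label, start, end)`` with half-open date
    ranges ``[start, end)``; overlapping periods are fatal.  Records outside
    every period are ignored.
    """
    parsed = [
        (label, pd.Timestamp(start), pd.Timestamp(end)) for label, start, end in periods
    ]
    for label, start, end in parsed:
        if not start < end:
            raise ValueError(f"period {label!r}: start must precede end")
    by_start = sorted(parsed, key=lambda p: p[1])
    for (l1, _, e1), (l2, s2, _) in zip(by_start, by_start[1:]):
        if e1 > s2:
            raise ValueError(f"periods {l1!r} and {l2!r} overlap")
    ts = pd.DatetimeIndex(records["datetime"])
    rows = []
    for label, start, end in parsed:
        sub = records[(ts >= start) & (ts < end)]
        for radar, rsub in sub.groupby("radar", sort=True):
            w = rsub["dens"].to_numpy(dtype=float)
            if w.sum() <= 0:
                continue
            u = rsub["u"].to_numpy(dtype=float)
            v = rsub["v"].to_numpy(dtype=float)
            U = rsub["U"].to_numpy(dtype=float)
            V = rsub["V"].to_numpy(dtype=float)
            row = {"radar": radar, "period": label}
            row.update(_vector_block("ground", u, v, w))
            row.update(_vector_block("air", u - U, v - V, w))
            row.update(_vector_block("wind", U, V, w))
            row["total_density"] = float(w.sum())
            row["n_records"] = int(len(rsub))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WindExposure:
    """Experienced (density-weighted) vs available (unweighted) wind stats."""

    experienced_W: WeightedStats
    available_W: WeightedStats
    experienced_wp: WeightedStats
    available_wp: WeightedStats


def experienced_vs_available(records: pd.DataFrame) -> WindExposure:
    """Contrast the wind birds flew in with the wind that was on offer.

    Experienced statistics weight every record by its bird density;
    available statistics weight all records equally.
    """
    if len(records) == 0:
        raise ValueError("experienced_vs_available: no records")
    w = records["dens"].to_numpy(dtype=float)
    ones = np.ones_like(w)
    W = records["W"].to_numpy(dtype=float)
    wp = records["wp"].to_numpy(dtype=float)
    return WindExposure(
        experienced_W=weighted_stats(W, w),
        available_W=weighted_stats(W, ones),
        experienced_wp=weighted_stats(wp, w),
        available_wp=weighted_stats(wp, ones),
    )
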