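"""Seasonal headline statistics.

Covers the weighted spring/autumn summaries of ground speed, airspeed,
wind speed and wind profit, the exceedance probability that a spring
airspeed beats an autumn airspeed under the exact (unbinned) weighted
empirical distributions, and the back-of-envelope migration ratios a
practitioner derives from seasonal and pooled means (how much wind speeds
up migration, and by how many flight hours over a typical journey).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import WeightedStats, weighted_stats

_QUANTITIES = ("Vg", "Va", "W", "wp")


def exceedance_probability(x_values, x_weights, y_values, y_weights) -> float:
    """P(X > Y) for independent draws from two weighted empirical
    distributions, counting ties as 1/2.

    Computed by sorting Y once and accumulating its weight CDF, so the cost
    is O((n+m) log(n+m)) instead of the O(n*m) double sum it equals:

        P = sum_i sum_j w_i v_j * [x_i > y_j] + 1/2 w_i v_j * [x_i = y_j]

    with both weight vectors normalized to 1.  Invariant to rescaling
    either weight vector by a positive constant.
    """
    x = np.asarray(x_values, dtype=float)
    wx = np.asarray(x_weights, dtype=float)
    y = np.asarray(y_values, dtype=float)
    wy = np.asarray(y_weights, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if np.any(wx < 0) or np.any(wy < 0):
        raise ValueError("negative weight")
    tx, ty = wx.sum(), wy.sum()
    if not (tx > 0 and ty > 0):
        raise ValueError("total weight must be positive")
    wx = wx / tx
    wy = wy / ty
    order = np.argsort(y, kind="mergesort")
    ys = y[order]
    cum = np.concatenate([[0.0], np.cumsum(wy[order])])
    below = cum[np.searchsorted(ys, x, side="left")]  # P(Y < x)
    at = cum[np.searchsorted(ys, x, side="right")] - below  # P(Y = x)
    return float(np.dot(wx, below + 0.5 * at))


@dataclass
class SeasonSummary:
    """Per-season and pooled weighted statistics plus the airspeed
    spring-over-autumn exceedance probability."""

    per_season: dict[str, dict[str, WeightedStats]]
    pooled: dict[str, WeightedStats]
    p_spring_faster: float

    def to_frame(self) -> pd.DataFrame:
        """Flat table (season x quantity -> mean, sd, total_weight, n)."""
        rows = []
        for season, stats in self.per_season.items():
            for q, s in stats.items():
                rows.append(
                    {"season": season, "quantity": q, "mean": s.mean, "sd": s.sd,
                     "total_weight": s.total_weight, "n": s.n}
                )
        for q, s in self.pooled.items():
            rows.append(
                {"season": "pooled", "quantity": q, "mean": s.mean, "sd": s.sd,
                 "total_weight": s.total_weight, "n": s.n}
            )
        return pd.DataFrame(rows)


def season_summary(records: pd.DataFrame, require_both: bool = True) -> SeasonSummary:
    """Density-weighted seasonal and pooled summaries of Vg, Va, W, wp.

    The exceedance probability uses the exact weighted empirical airspeed
    distributions of the two seasons.  By default a missing season is an
    error naming it; with ``require_both=False`` (single-season data sets)
    the absent season is simply omitted and the probability is NaN.
    """
    both = True
    for season in ("spring", "autumn"):
        if not (records["season"] == season).any():
            if require_both:
                raise ValueError(f"season_summary: no records for season {season!r}")
            both = False
    per_season: dict[str, dict[str, WeightedStats]] = {}
    for season, sub in records.groupby("season"):
        w = sub["dens"].to_numpy(dtype=float)
        per_season[str(season)] = {
            q: weighted_stats(sub[q].to_numpy(dtype=float), w) for q in _QUANTITIES
        }
    w_all = records["dens"].to_numpy(dtype=float)
    pooled = {q: weighted_stats(records[q].to_numpy(dtype=float), w_all) for q in _QUANTITIES}
    if both:
        sp = records[records["season"] == "spring"]
        au = records[records["season"] == "autumn"]
        p = exceedance_probability(
            sp["Va"].to_numpy(dtype=float),
            sp["dens"].to_numpy(dtype=float),
            au["Va"].to_numpy(dtype=float),
            au["dens"].to_numpy(dtype=float),
        )
    else:
        p = float("nan")
    return SeasonSummary(per_season=per_season, pooled=pooled, p_spring_faster=p)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class RatioReport:
    """Headline migration-speed ratios, at print precision.

    Percentages are rounded to the nearest integer, ratios to 2 decimals,
    hours to the nearest integer.  Fields whose inputs were not supplied
    are ``None``.
    """

    groundspeed_over_airspeed_pct: int | None = None
    wind_speedup_pct: int | None = None
    wind_speedup_spring_pct: int | None = None
    wind_speedup_autumn_pct: int | None = None
    groundspeed_season_ratio: float | None = None
    airspeed_season_ratio: float | None = None
    airspeed_season_ratio_pct: int | None = None
    flight_hours_saved: int | None = None

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "groundspeed_over_airspeed_pct": self.groundspeed_over_airspeed_pct,
            "wind_speedup_pct": self.wind_speedup_pct,
            "wind_speedup_spring_pct": self.wind_speedup_spring_pct,
            "wind_speedup_autumn_pct": self.wind_speedup_autumn_pct,
            "groundspeed_season_ratio": self.groundspeed_season_ratio,
            "airspeed_season_ratio": self.airspeed_season_ratio,
            "airspeed_season_ratio_pct": self.airspeed_season_ratio_pct,
            "flight_hours_saved": self.flight_hours_saved,
        }


def worked_ratios(
    vg: float | None = None,
    va: float | None = None,
    wp: float | None = None,
    vg_spring: float | None = None,
    vg_autumn: float | None = None,
    va_spring: float | None = None,
    va_autumn: float | None = None,
    wp_spring: float | None = None,
    wp_autumn: float | None = None,
    journey_km: float = 3000.0,
    journey_hours: float = 80.0,
) -> RatioReport:
    """Migration-speed ratios from pooled and seasonal mean speeds (m/s).

    - ``groundspeed_over_airspeed_pct`` = 100*(Vg/Va - 1): how much faster
      birds move over ground than through air.
    - ``wind_speedup_pct`` = 100*wp/Vg, pooled (and the per-season
      analogues): the share of ground speed contributed by wind profit.
    - ``groundspeed_season_ratio`` = Vg_spring/Vg_autumn (2 dp), and the
      airspeed analogue both as a 2-dp ratio and as a percent excess.
    - ``flight_hours_saved`` = journey_hours * wp/Vg: flight time the wind
      saves on a journey flown in ``journey_hours`` at ground speed Vg.

    Denominators must be positive; every ratio is invariant to a common
    rescaling of the speed units.
    """

    def _pct_of(num: float | None, den: float | None) -> int | None:
        if num is None or den is None:
            return None
        if den <= 0:
            raise ValueError("ratio denominator must be positive")
        return _round_half_up(100.0 * num / den)

    report = RatioReport(
        groundspeed_over_airspeed_pct=(
            None if vg is None or va is None else _pct_of(vg - va, va)
        ),
        wind_speedup_pct=_pct_of(wp, vg),
        wind_speedup_spring_pct=_pct_of(wp_spring, vg_spring),
        wind_speedup_autumn_pct=_pct_of(wp_autumn, vg_autumn),
        groundspeed_season_ratio=(
            None
            if vg_spring is None or vg_autumn is None
            else round(vg_spring / vg_autumn, 2)
        ),
        airspeed_season_ratio=(
            None
            if va_spring is None or va_autumn is None
            else round(va_spring / va_autumn, 2)
        ),
        airspeed_season_ratio_pct=(
            None if va_spring is None or va_autumn is None else _pct_of(va_spring - va_autumn, va_autumn)
        ),
        flight_hours_saved=(
            None
            if wp is None or vg is None
            else _round_half_up(journey_hours * wp / vg)
        ),
    )
    for name in ("groundspeed_season_ratio", "airspeed_season_ratio"):
        val = getattr(report, name)
        if val is not None and not np.isfinite(val):
            raise ValueError(f"{name}: non-finite result")
    return report


def ratios_from_summary(
    summary: SeasonSummary, journey_km: float = 3000.0, journey_hours: float = 80.0
) -> RatioReport:
    """Convenience: compute :func:`worked_ratios` from a SeasonSummary."""
    def _mean(season: str, q: str) -> float | None:
        stats = summary.per_season.get(season)
        return None if stats is None else stats[q].mean

    return worked_ratios(
        vg=summary.pooled["Vg"].mean,
        va=summary.pooled["Va"].mean,
        wp=summary.pooled["wp"].mean,
        vg_spring=_mean("spring", "Vg"),
        vg_autumn=_mean("autumn", "Vg"),
        va_spring=_mean("spring", "Va"),
        va_autumn=_mean("autumn", "Va"),
        wp_spring=_mean("spring", "wp"),
        wp_autumn=_mean("autumn", "wp"),
        journey_km=journey_km,
        journey_hours=journey_hours,
    )
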