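"""Solar-position helpers for day/night classification.

Implements the standard NOAA low-precision solar position algorithm
(fractional-year Fourier series for declination and the equation of time).
Accuracy is a few tenths of a degree in elevation, which is ample for
classifying nocturnal migration records: the same function is used both by
the synthetic-data generator and by the nightly aggregation, so the two
always agree on what counts as night.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def solar_elevation(times, latitude: float, longitude: float) -> np.ndarray:
    """Solar elevation angle in degrees at UTC instants ``times``.

    Parameters
    ----------
    times : datetime-like sequence
        Naive timestamps interpreted as UTC.
    latitude, longitude : float
        Observer position in decimal degrees.
    """
    ts = pd.DatetimeIndex(times)
    doy = ts.dayofyear.to_numpy(dtype=float)
    hour = (
        ts.hour.to_numpy(dtype=float)
        + ts.minute.to_numpy(dtype=float) / 60.0
        + ts.second.to_numpy(dtype=float) / 3600.0
    )
    gamma = 2.0 * np.pi / 365.0 * (doy - 1.0 + (hour - 12.0) / 24.0)

    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    # equation of time, minutes
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    tst = hour * 60.0 + eqtime + 4.0 * longitude  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle
    lat = np.radians(latitude)
    sin_elev = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))


def is_night(times, latitude: float, longitude: float) -> np.ndarray:
    """True where the sun is below the horizon (elevation < 0 deg)."""
    return solar_elevation(times, latitude, longitude) < 0.0


def night_date(times, longitude: float) -> np.ndarray:
    """Civil date of the evening a nocturnal record belongs to.

    Records after local solar noon keep their own date; records before it
    (small hours) are assigned to the previous date, so a night straddling
    midnight shares one id.  Local solar time is approximated as
    UTC + longitude/15 hours.
    """
    ts = pd.DatetimeIndex(times)
    local = ts + pd.Timedelta(hours=1) * (longitude / 15.0)
    date = local.normalize()
    before_noon = (local - date) < pd.Timedelta(hours=12)
    return (date - before_noon * pd.Timedelta(days=1)).to_numpy()
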