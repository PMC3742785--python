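"""Clear-sky photosynthetically active photon flux from solar geometry.

The within-day oxygen model only needs the *shape* of the diel light
curve — the photosynthesis–irradiance coefficient absorbs the absolute
scale — so light is modelled geometrically: photon flux is proportional
to the sine of solar elevation while the sun is up and zero otherwise,
assuming uniform atmospheric transparency.

Solar position uses the low-precision Spencer (1971) Fourier series for
declination and the equation of time (accurate to about 1 minute, ample
for a 30-minute sampling cadence). Timestamps are naive local standard
time; the site's UTC offset fixes the zone meridian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import SiteMeta

__all__ = ["LightModel", "solar_elevation", "sunrise_sunset"]

_DEG = np.pi / 180.0


def _day_angle(ts: pd.Timestamp) -> float:
    doy = ts.dayofyear
    frac = (ts.hour + ts.minute / 60 + ts.second / 3600) / 24.0
    return 2.0 * np.pi * (doy - 1 + frac) / 365.0


def _declination_rad(gamma: float) -> float:
    # Spencer (1971) series, radians
    return (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )


def _equation_of_time_min(gamma: float) -> float:
    # Spencer (1971) series, minutes
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )


def solar_elevation(site: SiteMeta, instant: pd.Timestamp) -> float:
    """Solar elevation angle in degrees at a naive local-standard-time instant.

    Returns a value in [-90, 90]; positive means the sun is above the
    horizon. No atmospheric refraction correction.
    """
    instant = pd.Timestamp(instant)
    gamma = _day_angle(instant)
    decl = _declination_rad(gamma)
    eot = _equation_of_time_min(gamma)
    zone_meridian = 15.0 * site.utc_offset_h
    # true solar time in hours
    clock_h = instant.hour + instant.minute / 60 + instant.second / 3600
    solar_h = clock_h + (4.0 * (site.longitude_dd - zone_meridian) + eot) / 60.0
    hour_angle = (solar_h - 12.0) * 15.0 * _DEG
    lat = site.latitude_dd * _DEG
    sin_el = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)
    return float(np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0))))


def sunrise_sunset(site: SiteMeta, date) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Local-standard-time sunrise and sunset for a calendar day.

    Finds the zero crossings of solar elevation by scanning the day in
    10-minute strides and refining by bisection to <= 1 minute. Raises
    ``ValueError`` if the sun never crosses the horizon (polar day or
    night — outside this package's tropical remit).
    """
    day0 = pd.Timestamp(date).normalize()

    def elev_at(minutes: float) -> float:
        return solar_elevation(site, day0 + pd.Timedelta(minutes=minutes))

    grid = np.arange(0.0, 24 * 60 + 1, 10.0)
    el = np.array([elev_at(m) for m in grid])
    rise = sset = None
    for i in range(len(grid) - 1):
        if el[i] < 0 <= el[i + 1] and rise is None:
            rise = brentq(elev_at, grid[i], grid[i + 1], xtol=0.5)
        if el[i] >= 0 > el[i + 1] and sset is None:
            sset = brentq(elev_at, grid[i], grid[i + 1], xtol=0.5)
    if rise is None or sset is None:
        raise ValueError(f"no sunrise/sunset crossing on {day0.date()} at this site")
    return (day0 + pd.Timedelta(minutes=float(rise)),
            day0 + pd.Timedelta(minutes=float(sset)))


@dataclass(frozen=True)
class LightModel:
    """Photon flux Q_p(t) = peak_qp * max(0, sin(solar elevation)).

    ``peak_qp`` is the flux at zero zenith angle, default 2000
    µmol photons m⁻² s⁻¹ (a typical tropical clear-sky peak PAR).
    """

    site: SiteMeta
    peak_qp: float = 2000.0

    def __post_init__(self) -> None:
        if self.peak_qp <= 0:
            raise ValueError("peak_qp must be > 0")

    def qp_at(self, instant) -> float:
        el = solar_elevation(self.site, pd.Timestamp(instant))
        return self.peak_qp * max(0.0, float(np.sin(el * _DEG)))

    def qp_series(self, times: pd.DatetimeIndex) -> np.ndarray:
        return np.array([self.qp_at(t) for t in times])
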