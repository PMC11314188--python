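"""Daily weather records and FAO-56 reference evapotranspiration.

Crop water demand is computed in two steps: reference evapotranspiration
ET0 of a standard grass surface from daily weather (Penman-Monteith,
FAO-56 daily formulation), then scaling by a staged crop coefficient Kc.
The simulator runs on a daily timestep only.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

__all__ = [
    "DailyWeather", "Site", "KcCurve",
    "reference_et", "crop_kc", "crop_et_demand",
    "saturation_vapour_pressure", "svp_slope", "psychrometric_constant",
    "extraterrestrial_radiation", "net_radiation", "penman_monteith_daily",
]

#: Solar constant, MJ m-2 min-1.
_GSC = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1.
_SIGMA = 4.903e-9
#: Reference-surface albedo.
_ALBEDO = 0.23


@dataclass(frozen=True)
class Site:
    """Geographic location of the simulated field."""

    latitude: float  # decimal degrees, positive north
    altitude: float = 0.0  # m above sea level

    def __post_init__(self) -> None:
        if not abs(self.latitude) <= 90:
            raise ValueError(f"latitude out of range: {self.latitude}")


@dataclass(frozen=True)
class DailyWeather:
    """One day of weather forcing.

    Humidity may be given either as mean relative humidity ``rh_mean``
    (percent) or directly as actual vapour pressure ``ea`` (kPa); at
    least one is required for reference ET.
    """

    date: _dt.date
    tmax: float  # deg C
    tmin: float  # deg C
    solar_rad: float  # MJ m-2 d-1
    wind2: float  # m s-1 at 2 m height
    rain: float  # mm d-1
    rh_mean: float | None = None  # %
    ea: float | None = None  # kPa

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"{self.date}: tmax {self.tmax} < tmin {self.tmin}")
        if self.rain < 0:
            raise ValueError(f"{self.date}: negative rain")
        if self.solar_rad < 0:
            raise ValueError(f"{self.date}: negative solar radiation")
        if self.wind2 < 0:
            raise ValueError(f"{self.date}: negative wind speed")
        if self.rh_mean is not None and not 0 <= self.rh_mean <= 100:
            raise ValueError(f"{self.date}: rh_mean {self.rh_mean} outside [0, 100]")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)

    def actual_vapour_pressure(self) -> float:
        """Actual vapour pressure in kPa, from ``ea`` or ``rh_mean``."""
        if self.ea is not None:
            return self.ea
        if self.rh_mean is None:
            raise ValueError(
                f"{self.date}: no humidity information (rh_mean or ea required)"
            )
        es = 0.5 * (
            saturation_vapour_pressure(self.tmax)
            + saturation_vapour_pressure(self.tmin)
        )
        return self.rh_mean / 100.0 * es


def saturation_vapour_pressure(t: float) -> float:
    """Saturation vapour pressure e0(T) in kPa at air temperature T (deg C)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def svp_slope(t: float) -> float:
    """Slope of the saturation vapour pressure curve, kPa per deg C."""
    return 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2


def psychrometric_constant(altitude: float) -> float:
    """Psychrometric constant gamma (kPa per deg C) at a given altitude."""
    pressure = 101.3 * ((293.0 - 0.0065 * altitude) / 293.0) ** 5.26
    return 0.665e-3 * pressure


def extraterrestrial_radiation(day_of_year: int, latitude: float) -> float:
    """Daily extraterrestrial radiation Ra, MJ m-2 d-1."""
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * day_of_year / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    return (
        24.0 * 60.0 / math.pi * _GSC * dr
        * (ws * math.sin(phi) * math.sin(delta)
           + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )


def net_radiation(day: DailyWeather, site: Site) -> float:
    """Net radiation at the grass reference surface, MJ m-2 d-1.

    Shortwave from measured solar radiation with albedo 0.23; longwave
    from the FAO-56 clear-sky/cloudiness correction.
    """
    doy = day.date.timetuple().tm_yday
    ra = extraterrestrial_radiation(doy, site.latitude)
    rso = (0.75 + 2e-5 * site.altitude) * ra
    rns = (1.0 - _ALBEDO) * day.solar_rad
    ea = day.actual_vapour_pressure()
    rel = 1.0 if rso <= 0 else min(day.solar_rad / rso, 1.0)
    rnl = (
        _SIGMA
        * 0.5 * ((day.tmax + 273.16) ** 4 + (day.tmin + 273.16) ** 4)
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    return rns - rnl


def penman_monteith_daily(
    tmean: float, rn: float, u2: float, es: float, ea: float, gamma: float
) -> float:
    """FAO-56 daily Penman-Monteith combination equation, mm d-1.

    Soil heat flux is taken as zero at the daily step. Negative results
    (possible on cold, radiation-deficit days) clamp to zero.
    """
    delta = svp_slope(tmean)
    num = 0.408 * delta * rn + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return max(0.0, num / den)


def reference_et(day: DailyWeather, site: Site) -> float:
    """Grass reference evapotranspiration ET0 (mm d-1) for one day."""
    es = 0.5 * (
        saturation_vapour_pressure(day.tmax)
        + saturation_vapour_pressure(day.tmin)
    )
    ea = day.actual_vapour_pressure()
    rn = net_radiation(day, site)
    gamma = psychrometric_constant(site.altitude)
    return penman_monteith_daily(day.tmean, rn, day.wind2, es, ea, gamma)


@dataclass(frozen=True)
class KcCurve:
    """Four-stage FAO-style crop coefficient curve.

    The season is split into initial, development, mid and late stages
    by fractional lengths summing to one. Kc is kc_ini on the initial
    plateau, ramps linearly to kc_mid across development, holds kc_mid
    through mid-season, and ramps to kc_end across the late stage.
    """

    kc_ini: float
    kc_mid: float
    kc_end: float
    f_ini: float = 0.2
    f_dev: float = 0.3
    f_mid: float = 0.3
    f_late: float = 0.2

    def __post_init__(self) -> None:
        for kc in (self.kc_ini, self.kc_mid, self.kc_end):
            if kc < 0:
                raise ValueError("crop coefficients must be non-negative")
        fracs = (self.f_ini, self.f_dev, self.f_mid, self.f_late)
        if any(not 0 < f <= 1 for f in fracs):
            raise ValueError("stage fractions must lie in (0, 1]")
        if not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
            raise ValueError(f"stage fractions sum to {sum(fracs)}, not 1")


def crop_kc(day_of_season: float, curve: KcCurve) -> float:
    """Crop coefficient at a fractional position in [0, 1] of the season."""
    if not 0.0 <= day_of_season <= 1.0:
        raise ValueError(f"day_of_season {day_of_season} outside [0, 1]")
    f = day_of_season
    b1 = curve.f_ini
    b2 = b1 + curve.f_dev
    b3 = b2 + curve.f_mid
    if f <= b1:
        return curve.kc_ini
    if f <= b2:
        w = (f - b1) / curve.f_dev
        return curve.kc_ini + w * (curve.kc_mid - curve.kc_ini)
    if f <= b3:
        return curve.kc_mid
    w = (f - b3) / curve.f_late
    return curve.kc_mid + w * (curve.kc_end - curve.kc_mid)


def crop_et_demand(et0: float, kc: float) -> float:
    """Potential crop evapotranspiration, mm d-1."""
    if et0 < 0 or kc < 0:
        raise ValueError("et0 and kc must be non-negative")
    return et0 * kc
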