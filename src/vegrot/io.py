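"""File formats: weather, soil profile, management schedule, run config.

All on-disk formats are delimited text (tab-separated) with a header
row and ISO-8601 dates. The soil table mirrors the usual profile-pit
reporting (layer bounds, texture fractions, bulk density, hydraulic
limits, pH). Management schedules are flat event lists.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .soilwater import SoilLayer, SoilProfile
from .weather import DailyWeather

__all__ = [
    "ManagementEvent", "EVENT_KINDS",
    "read_weather", "write_weather", "read_soil", "write_soil",
    "read_management", "write_management",
]

EVENT_KINDS = ("irrigation", "urea", "manure", "sowing", "harvest")


@dataclass(frozen=True)
class ManagementEvent:
    """One field operation.

    ``amount`` is mm for irrigation and kg N ha-1 for urea or manure;
    sowing and harvest carry the crop name instead. Manure may be
    incorporated by tillage (reduced ammonia loss).
    """

    date: _dt.date
    kind: str
    amount: float = 0.0
    crop: str = ""
    incorporated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.amount < 0:
            raise ValueError(f"{self.date} {self.kind}: negative amount")


_WEATHER_COLS = ["date", "tmax", "tmin", "rh_mean", "wind2", "solar_rad", "rain"]


def write_weather(days: Iterable[DailyWeather], path) -> None:
    rows = [
        {"date": d.date.isoformat(), "tmax": d.tmax, "tmin": d.tmin,
         "rh_mean": d.rh_mean, "wind2": d.wind2, "solar_rad": d.solar_rad,
         "rain": d.rain}
        for d in days
    ]
    pd.DataFrame(rows, columns=_WEATHER_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_weather(path) -> list[DailyWeather]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _WEATHER_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing weather columns {missing}")
    if df[_WEATHER_COLS].isna().any().any():
        bad = df[df[_WEATHER_COLS].isna().any(axis=1)].index[0]
        raise ValueError(f"{path}: missing value in weather row {bad}")
    return [
        DailyWeather(
            date=_dt.date.fromisoformat(str(r.date)), tmax=float(r.tmax),
            tmin=float(r.tmin), rh_mean=float(r.rh_mean), wind2=float(r.wind2),
            solar_rad=float(r.solar_rad), rain=float(r.rain))
        for r in df.itertuples()
    ]


_SOIL_COLS = ["top", "bottom", "sand", "silt", "clay", "texture",
              "bulk_density", "theta_fc", "theta_wp", "theta_s", "ph"]


def write_soil(rows: Sequence[tuple], path) -> None:
    """Write a soil table; ``rows`` as in the profile-pit tuple layout."""
    pd.DataFrame(list(rows), columns=_SOIL_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_soil(path) -> SoilProfile:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _SOIL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing soil columns {missing}")
    layers = tuple(
        SoilLayer(top=float(r.top), bottom=float(r.bottom),
                  bulk_density=float(r.bulk_density), theta_s=float(r.theta_s),
                  theta_fc=float(r.theta_fc), theta_wp=float(r.theta_wp))
        for r in df.itertuples()
    )
    return SoilProfile(layers)


def write_management(events: Iterable[ManagementEvent], path) -> None:
    rows = [
        {"date": e.date.isoformat(), "type": e.kind, "amount": e.amount,
         "unit": "mm" if e.kind == "irrigation" else
                 ("kgN/ha" if e.kind in ("urea", "manure") else ""),
         "crop": e.crop, "incorporated": int(e.incorporated)}
        for e in events
    ]
    pd.DataFrame(rows, columns=["date", "type", "amount", "unit", "crop",
                                "incorporated"]).to_csv(path, sep="\t", index=False,
                                            float_format="%.17g")


def read_management(path) -> list[ManagementEvent]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     float_precision="round_trip")
    events = []
    for r in df.itertuples():
        events.append(ManagementEvent(
            date=_dt.date.fromisoformat(str(r.date)), kind=str(r.type),
            amount=float(r.amount), crop=str(r.crop),
            incorporated=bool(int(r.incorporated)) if str(r.incorporated) else False))
    return sorted(events, key=lambda e: e.date)
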