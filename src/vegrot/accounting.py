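"""Seasonal and annual water / nitrogen ledgers with efficiency indices.

Conventions follow the field-experiment reporting style for a 0.9 m
profile:

    WUE  = Y / ET            (kg fresh yield per m3 of evapotranspiration)
    IWUE = Y / I             (kg per m3 of irrigation)
    Wbalance = RF + I - ET - D                       (mm, storage change)
    NUE  = Y / (Nup + Nlea + Ngas)                   (kg fresh per kg N)
    Nbalance = (Manu + Fert + Nirr + Nnet) - (Nup + Ngas + Nlea)

Yields are kg ha-1 and water depths mm; 1 mm over 1 ha is 10 m3, so the
kg m-3 efficiencies divide yield by 10x the depth. Annual rows sum the
extensive fields of their seasons and recompute every ratio from the
sums (never averaging per-season ratios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["SeasonBalance", "season_water_balance", "season_n_balance",
           "combine_balance", "aggregate_annual", "write_balance_report",
           "MM_HA_TO_M3"]

#: Cubic metres of water in 1 mm depth over 1 ha.
MM_HA_TO_M3 = 10.0

_WATER_EXTENSIVE = ("rainfall", "irrigation", "et", "drainage", "yield_fresh")
_N_EXTENSIVE = ("manure_n", "fertilizer_n", "irrigation_n", "net_mineralization",
                "uptake_n", "gaseous_n", "leached_n")


@dataclass
class SeasonBalance:
    """Water and nitrogen ledger for one treatment-season (or its annual sum).

    Efficiency ratios that are undefined (zero denominator) are ``None``,
    never silently zero.
    """

    treatment: str = ""
    crop: str = ""
    year: int = 0
    # water side (mm except yield)
    rainfall: float = 0.0
    irrigation: float = 0.0
    et: float = 0.0
    drainage: float = 0.0
    yield_fresh: float = 0.0   # kg ha-1
    wue: float | None = None   # kg m-3
    iwue: float | None = None  # kg m-3
    wbalance: float | None = None  # mm
    # nitrogen side (kg N ha-1)
    manure_n: float = 0.0
    fertilizer_n: float = 0.0
    irrigation_n: float = 0.0
    net_mineralization: float = 0.0
    uptake_n: float = 0.0
    gaseous_n: float = 0.0
    leached_n: float = 0.0
    nue: float | None = None   # kg kg-1
    nbalance: float | None = None  # kg N ha-1


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def season_water_balance(
    rainfall: float, irrigation: float, et: float, drainage: float,
    yield_fresh: float, *, treatment: str = "", crop: str = "", year: int = 0,
) -> SeasonBalance:
    """Fill the water side of a ledger row from its components."""
    for name, v in (("rainfall", rainfall), ("irrigation", irrigation),
                    ("et", et), ("drainage", drainage), ("yield", yield_fresh)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return SeasonBalance(
        treatment=treatment, crop=crop, year=year,
        rainfall=rainfall, irrigation=irrigation, et=et, drainage=drainage,
        yield_fresh=yield_fresh,
        wue=_ratio(yield_fresh, et * MM_HA_TO_M3),
        iwue=_ratio(yield_fresh, irrigation * MM_HA_TO_M3),
        wbalance=rainfall + irrigation - et - drainage,
    )


def season_n_balance(
    manure_n: float, fertilizer_n: float, irrigation_n: float,
    net_mineralization: float, uptake_n: float, gaseous_n: float,
    leached_n: float, yield_fresh: float, *,
    treatment: str = "", crop: str = "", year: int = 0,
) -> SeasonBalance:
    """Fill the nitrogen side of a ledger row from its components."""
    for name, v in (("manure_n", manure_n), ("fertilizer_n", fertilizer_n),
                    ("irrigation_n", irrigation_n), ("uptake_n", uptake_n),
                    ("gaseous_n", gaseous_n), ("leached_n", leached_n)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    outputs = uptake_n + gaseous_n + leached_n
    inputs = manure_n + fertilizer_n + irrigation_n + net_mineralization
    return SeasonBalance(
        treatment=treatment, crop=crop, year=year,
        manure_n=manure_n, fertilizer_n=fertilizer_n, irrigation_n=irrigation_n,
        net_mineralization=net_mineralization, uptake_n=uptake_n,
        gaseous_n=gaseous_n, leached_n=leached_n, yield_fresh=yield_fresh,
        nue=_ratio(yield_fresh, outputs),
        nbalance=inputs - outputs,
    )


def combine_balance(water: SeasonBalance, nitrogen: SeasonBalance) -> SeasonBalance:
    """Merge a water-side and an N-side row for the same season."""
    if (water.treatment, water.crop, water.year) != (
            nitrogen.treatment, nitrogen.crop, nitrogen.year):
        raise ValueError("rows describe different seasons")
    merged = season_water_balance(
        water.rainfall, water.irrigation, water.et, water.drainage,
        water.yield_fresh, treatment=water.treatment, crop=water.crop,
        year=water.year)
    n = season_n_balance(
        nitrogen.manure_n, nitrogen.fertilizer_n, nitrogen.irrigation_n,
        nitrogen.net_mineralization, nitrogen.uptake_n, nitrogen.gaseous_n,
        nitrogen.leached_n, water.yield_fresh, treatment=water.treatment,
        crop=water.crop, year=water.year)
    for f in _N_EXTENSIVE + ("nue", "nbalance"):
        setattr(merged, f, getattr(n, f))
    return merged


def aggregate_annual(seasons: Sequence[SeasonBalance]) -> SeasonBalance:
    """Sum the seasons of one treatment-year and recompute every ratio.

    Extensive fields (depths, masses, yield) add; WUE, IWUE, NUE,
    Wbalance and Nbalance are recomputed from the sums.
    """
    if not seasons:
        raise ValueError("no seasons to aggregate")
    keys = {(s.treatment, s.year) for s in seasons}
    if len(keys) > 1:
        raise ValueError(f"cannot aggregate across treatment-years: {sorted(keys)}")
    tot = {f: sum(getattr(s, f) for s in seasons)
           for f in _WATER_EXTENSIVE + _N_EXTENSIVE}
    water = season_water_balance(
        tot["rainfall"], tot["irrigation"], tot["et"], tot["drainage"],
        tot["yield_fresh"], treatment=seasons[0].treatment, crop="total",
        year=seasons[0].year)
    nitro = season_n_balance(
        tot["manure_n"], tot["fertilizer_n"], tot["irrigation_n"],
        tot["net_mineralization"], tot["uptake_n"], tot["gaseous_n"],
        tot["leached_n"], tot["yield_fresh"], treatment=seasons[0].treatment,
        crop="total", year=seasons[0].year)
    return combine_balance(water, nitro)


_WATER_COLS = ("RF", "I", "ET", "D", "Y", "WUE", "IWUE", "Wbalance")
_N_COLS = ("Manu", "Fert", "Nirr", "Nnet", "Nup", "Ngas", "Nlea", "NUE", "Nbalance")
_FIELD_OF = {
    "RF": "rainfall", "I": "irrigation", "ET": "et", "D": "drainage",
    "Y": "yield_fresh", "WUE": "wue", "IWUE": "iwue", "Wbalance": "wbalance",
    "Manu": "manure_n", "Fert": "fertilizer_n", "Nirr": "irrigation_n",
    "Nnet": "net_mineralization", "Nup": "uptake_n", "Ngas": "gaseous_n",
    "Nlea": "leached_n", "NUE": "nue", "Nbalance": "nbalance",
}


def write_balance_report(
    rows: Iterable[SeasonBalance], path, *, side: str = "water",
    rounded: bool = False,
) -> None:
    """Write a delimited balance table (tab-separated).

    ``side`` selects the water-column order (RF, I, ET, D, Y, WUE, IWUE,
    Wbalance) or the N-column order (Manu, Fert, Nirr, Nnet, Nup, Ngas,
    Nlea, NUE, Nbalance). ``rounded`` emits one decimal place (yields to
    the nearest 100 kg ha-1) in the publication style instead of full
    precision.
    """
    cols = _WATER_COLS if side == "water" else _N_COLS
    if side not in ("water", "nitrogen"):
        raise ValueError("side must be 'water' or 'nitrogen'")
    with open(path, "w") as fh:
        fh.write("\t".join(("treatment", "crop", "year") + cols) + "\n")
        for r in rows:
            cells = [r.treatment, r.crop, str(r.year)]
            for c in cols:
                v = getattr(r, _FIELD_OF[c])
                if v is None:
                    cells.append("NA")
                elif rounded and c == "Y":
                    cells.append(f"{round(v / 100) * 100:.0f}")
                elif rounded:
                    cells.append(f"{v:.1f}")
                else:
                    cells.append(repr(float(v)))
            fh.write("\t".join(cells) + "\n")
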