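"""Vegetable growth: expolinear dry-matter gain, dilution-curve N demand.

Growth follows an expolinear curve (exponential early, linear once the
canopy closes): the potential daily gain is
``cm / (1 + exp(-rm (t - tb)))`` with maximum rate ``cm`` (t ha-1 d-1),
relative rate ``rm`` (d-1) and inflection day ``tb``; the closed form of
the cumulative curve is ``(cm/rm) log(1 + exp(rm (t - tb)))``. The
actual gain is the potential times the most limiting of the water and
nitrogen stress factors and a temperature factor (base 4 deg C).

Nitrogen demand follows a critical dilution curve: the minimum whole-
plant N concentration for unrestricted growth is ``a DM^-b`` percent of
dry matter (capped at the seedling plateau below 1 t ha-1), and crops
may take up luxury N to ``L`` times the critical concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .weather import KcCurve

__all__ = [
    "CropParams", "CropState", "DEFAULT_CROPS",
    "potential_growth_rate", "expolinear_dm", "temperature_growth_factor",
    "grow_daily", "critical_n_pct", "n_demand", "n_stress", "fresh_yield",
]


@dataclass(frozen=True)
class CropParams:
    """Parameter block for one vegetable.

    Dilution coefficients ``dilution_a`` (percent N at 1 t ha-1) and
    ``dilution_b`` follow the usual power-law convention; ``luxury_l``
    is the luxury-consumption ceiling relative to the critical curve.
    """

    name: str
    kc: KcCurve
    max_root_depth: float          # cm
    root_growth_rate: float        # cm d-1
    growth_cm: float               # maximum daily DM gain, t ha-1 d-1
    growth_rm: float               # relative growth rate in the lag, d-1
    growth_tb: float               # inflection day of the expolinear curve
    dilution_a: float              # %N at DM = 1 t ha-1
    dilution_b: float
    luxury_l: float                # >= 1
    seedling_n_pct: float          # plateau below 1 t ha-1 DM
    harvest_index: float           # harvested fraction of DM
    fresh_per_dry: float           # kg fresh per kg harvested dry matter
    initial_dm: float = 0.001      # t ha-1 at sowing/transplanting
    base_temp: float = 4.0         # deg C
    opt_temp: float = 18.0         # deg C at which growth is unconstrained

    def __post_init__(self) -> None:
        if self.dilution_a <= 0 or not 0 <= self.dilution_b < 1:
            raise ValueError("require a > 0 and 0 <= b < 1")
        if self.luxury_l < 1:
            raise ValueError("luxury coefficient must be >= 1")
        if self.fresh_per_dry <= 0 or self.harvest_index <= 0:
            raise ValueError("conversion factors must be positive")


@dataclass
class CropState:
    """Running state of the standing crop."""

    days_since_sowing: int = 0
    dry_matter: float = 0.0        # t ha-1
    plant_n: float = 0.0           # kg N ha-1, cumulative uptake
    root_depth: float = 0.0        # cm


def potential_growth_rate(t: float, params: CropParams) -> float:
    """Potential DM gain (t ha-1 d-1) on day ``t`` of the season."""
    z = params.growth_rm * (t - params.growth_tb)
    # logistic-shaped rate; guard the exponential for large |z|
    if z > 50:
        return params.growth_cm
    if z < -50:
        return params.growth_cm * math.exp(z)
    return params.growth_cm / (1.0 + math.exp(-z))


def expolinear_dm(t: float, params: CropParams) -> float:
    """Closed-form potential DM (t ha-1) after ``t`` unstressed days.

    Integral of :func:`potential_growth_rate` from 0 to ``t`` plus the
    initial dry matter; used as the analytic oracle for the daily loop.
    """
    def antideriv(x: float) -> float:
        z = params.growth_rm * (x - params.growth_tb)
        if z > 50:
            return params.growth_cm * (x - params.growth_tb)
        return params.growth_cm / params.growth_rm * math.log1p(math.exp(z))
    return params.initial_dm + antideriv(t) - antideriv(0.0)


def temperature_growth_factor(tmean: float, params: CropParams) -> float:
    """Linear ramp from 0 at the base temperature to 1 at the optimum."""
    if tmean <= params.base_temp:
        return 0.0
    return min(1.0, (tmean - params.base_temp) / (params.opt_temp - params.base_temp))


def critical_n_pct(dm: float, params: CropParams) -> float:
    """Critical (minimum non-limiting) plant N, percent of dry matter."""
    if dm < 0:
        raise ValueError("dry matter must be non-negative")
    if dm <= 0.0:
        return params.seedling_n_pct
    value = params.dilution_a * dm ** (-params.dilution_b)
    if dm < 1.0:
        return min(params.seedling_n_pct, value)
    return value


def n_stress(state: CropState, params: CropParams) -> float:
    """N sufficiency in [0, 1]: actual over critical concentration."""
    if state.dry_matter <= 0:
        return 1.0
    actual_pct = state.plant_n / (state.dry_matter * 10.0)
    crit = critical_n_pct(state.dry_matter, params)
    return min(1.0, max(0.0, actual_pct / crit))


def n_demand(state: CropState, params: CropParams, dm_next: float) -> float:
    """Daily N uptake demand (kg N ha-1 d-1) to reach the luxury ceiling.

    The target is ``L x critical%N(dm_next) x dm_next`` converted from
    (t ha-1, percent) to kg ha-1 (factor 10); demand is the shortfall
    relative to current plant N, floored at zero.
    """
    target_pct = params.luxury_l * critical_n_pct(dm_next, params)
    target_n = target_pct * dm_next * 10.0
    return max(0.0, target_n - state.plant_n)


def grow_daily(
    state: CropState,
    params: CropParams,
    water_stress: float = 1.0,
    nitrogen_stress: float | None = None,
    tmean: float | None = None,
) -> CropState:
    """Advance the crop one day.

    The DM increment is the potential expolinear gain scaled by
    ``min(water_stress, nitrogen_stress)`` and, when ``tmean`` is given,
    by the temperature factor. Root depth advances linearly to the
    maximum. The returned state does not include the day's N uptake;
    callers add the realised uptake to ``plant_n`` separately.
    """
    if nitrogen_stress is None:
        nitrogen_stress = n_stress(state, params)
    for s in (water_stress, nitrogen_stress):
        if not 0.0 <= s <= 1.0 + 1e-12:
            raise ValueError(f"stress factor {s} outside [0, 1]")
    ftemp = 1.0 if tmean is None else temperature_growth_factor(tmean, params)
    t = float(state.days_since_sowing)
    # exact integral of the expolinear rate over [t, t+1], so the
    # unstressed daily loop reproduces the closed-form curve
    potential = expolinear_dm(t + 1.0, params) - expolinear_dm(t, params)
    gain = potential * min(water_stress, nitrogen_stress) * ftemp
    return CropState(
        days_since_sowing=state.days_since_sowing + 1,
        dry_matter=state.dry_matter + gain,
        plant_n=state.plant_n,
        root_depth=min(params.max_root_depth,
                       state.root_depth + params.root_growth_rate),
    )


def fresh_yield(state: CropState, params: CropParams) -> float:
    """Marketable fresh yield (kg ha-1) at harvest."""
    return state.dry_matter * params.harvest_index * params.fresh_per_dry * 1000.0


def _kc(ini: float, mid: float, end: float) -> KcCurve:
    return KcCurve(kc_ini=ini, kc_mid=mid, kc_end=end)


#: Default parameter sets for the three rotation vegetables. The growth,
#: dilution and luxury coefficients are calibratable starting points
#: sized to the measured yield magnitudes (cauliflower ~2e4 kg ha-1
#: fresh over ~60 d; amaranth and spinach shorter and leafier), not
#: field-fitted constants.
DEFAULT_CROPS: dict[str, CropParams] = {
    "cauliflower": CropParams(
        name="cauliflower", kc=_kc(0.7, 1.05, 0.95), max_root_depth=50.0,
        root_growth_rate=1.0, growth_cm=0.130, growth_rm=0.18, growth_tb=28.0,
        dilution_a=4.0, dilution_b=0.30, luxury_l=1.15, seedling_n_pct=5.0,
        harvest_index=0.75, fresh_per_dry=8.0, initial_dm=0.05,
    ),
    "amaranth": CropParams(
        name="amaranth", kc=_kc(0.6, 1.0, 0.95), max_root_depth=30.0,
        root_growth_rate=1.2, growth_cm=0.110, growth_rm=0.25, growth_tb=14.0,
        dilution_a=4.5, dilution_b=0.25, luxury_l=1.2, seedling_n_pct=5.5,
        harvest_index=0.85, fresh_per_dry=12.0, initial_dm=0.005,
    ),
    "spinach": CropParams(
        name="spinach", kc=_kc(0.6, 1.0, 0.95), max_root_depth=30.0,
        root_growth_rate=0.8, growth_cm=0.140, growth_rm=0.22, growth_tb=16.0,
        dilution_a=4.8, dilution_b=0.25, luxury_l=1.2, seedling_n_pct=5.5,
        harvest_index=0.85, fresh_per_dry=11.0, initial_dm=0.005,
    ),
}
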