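"""Per-layer soil nitrogen pools and transformations.

Mineral N is tracked as urea, ammonium and nitrate per soil layer, plus
two first-order organic pools (added manure and native humus). Daily
transformations: organic-matter mineralisation (two-pool, first order,
temperature and moisture modified), urea hydrolysis, ammonia
volatilisation from the surface layer, nitrification, denitrification
above a water-filled-pore-space threshold, mixing-cell nitrate
advection with the day's drainage fluxes, and proportional plant
uptake. All masses in kg N ha-1, all rates per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .soilwater import SoilLayer, SoilProfile, proportional_allocation

__all__ = [
    "NPoolState", "NFluxDay", "NRateParams",
    "temperature_factor", "moisture_factor",
    "mineralize", "hydrolyze_urea", "volatilize", "nitrify", "denitrify",
    "advect_nitrate", "plant_uptake_n",
]


@dataclass
class NRateParams:
    """Rate constants and response-curve parameters for N transformations.

    All first-order constants are d-1 at the 20 deg C reference
    temperature and optimal moisture; they are the knobs exposed to the
    calibration harness.
    """

    k_humus: float = 6e-5          # humus mineralisation
    k_manure: float = 2e-2         # added-organic (manure) mineralisation
    k_hydrolysis: float = 0.36     # urea -> ammonium (half-life < 2 d)
    k_nitrification: float = 0.2   # ammonium -> nitrate
    k_denitrification: float = 0.1 # nitrate -> gas, at saturation
    wfps_threshold: float = 0.6    # denitrification onset (theta/theta_s)
    denit_exponent: float = 2.0    # power on excess WFPS
    q10: float = 2.0               # temperature sensitivity
    t_ref: float = 20.0            # deg C
    volat_fraction: float = 0.15   # surface NH4 volatilised on day 0
    volat_decay: float = 0.5       # per-day decay of that fraction
    volat_water_suppression: float = 0.1  # multiplier when water applied
    volat_water_threshold_mm: float = 5.0
    volat_incorporated_factor: float = 0.2  # incorporated manure
    uptake_extractable_fraction: float = 0.5  # of rooted mineral N per day
    immobilization: float = 0.0    # subtracted from gross humus release


@dataclass
class NPoolState:
    """Per-layer nitrogen pools (kg N ha-1 in each layer)."""

    urea: np.ndarray
    nh4: np.ndarray
    no3: np.ndarray
    manure_organic: np.ndarray
    humus: np.ndarray

    @classmethod
    def zeros(cls, n_layers: int) -> "NPoolState":
        z = lambda: np.zeros(n_layers)
        return cls(z(), z(), z(), z(), z())

    def copy(self) -> "NPoolState":
        return NPoolState(*(a.copy() for a in (
            self.urea, self.nh4, self.no3, self.manure_organic, self.humus)))

    @property
    def mineral(self) -> np.ndarray:
        return self.urea + self.nh4 + self.no3

    def total(self) -> float:
        return float(sum(a.sum() for a in (
            self.urea, self.nh4, self.no3, self.manure_organic, self.humus)))

    def check_nonnegative(self, tol: float = -1e-12) -> None:
        for name in ("urea", "nh4", "no3", "manure_organic", "humus"):
            arr = getattr(self, name)
            if (arr < tol).any():
                raise ValueError(f"negative {name} pool: min {arr.min()}")


@dataclass
class NFluxDay:
    """One day's nitrogen ledger entries (kg N ha-1 d-1)."""

    net_mineralization: float = 0.0  # humus release minus immobilisation
    manure_mineralization: float = 0.0
    hydrolysis: float = 0.0
    volatilization: float = 0.0
    nitrification: float = 0.0
    denitrification: float = 0.0
    leaching_report: float = 0.0   # nitrate past the reporting plane
    leaching_bottom: float = 0.0   # nitrate out of the simulated column
    uptake: float = 0.0
    n_in_irrigation: float = 0.0
    fertilizer_applied: float = 0.0
    manure_applied: float = 0.0

    @property
    def gaseous(self) -> float:
        return self.volatilization + self.denitrification


def temperature_factor(temp: float, params: NRateParams) -> float:
    """Q10-style rate multiplier, clipped to [0, 1] at the reference."""
    if temp <= 0.0:
        return 0.0
    f = params.q10 ** ((temp - params.t_ref) / 10.0)
    return float(min(f, 1.0))


def moisture_factor(theta: float, layer: SoilLayer, wet_floor: float = 0.5) -> float:
    """Moisture rate multiplier in [0, 1].

    Rises linearly from zero at wilting point to one at field capacity,
    then declines linearly toward ``wet_floor`` at saturation (aeration
    limitation).
    """
    if theta <= layer.theta_wp:
        return 0.0
    if theta <= layer.theta_fc:
        return (theta - layer.theta_wp) / (layer.theta_fc - layer.theta_wp)
    if theta >= layer.theta_s:
        return wet_floor
    frac = (theta - layer.theta_fc) / (layer.theta_s - layer.theta_fc)
    return 1.0 - (1.0 - wet_floor) * frac


def mineralize(
    pool_n: float, k: float, temp: float, theta: float,
    layer: SoilLayer, params: NRateParams,
) -> float:
    """First-order release from one organic pool, kg N ha-1 d-1.

    The daily step integrates the decay exactly:
    ``pool x (1 - exp(-k f_T f_theta))``, so that with constant rate
    factors the cumulative release over t days is the closed-form
    ``pool x (1 - exp(-k t))`` (and the flux can never exceed the pool).
    For small rates this is the usual ``pool k f_T f_theta`` product.
    """
    if pool_n < 0:
        raise ValueError("organic pool must be non-negative")
    k_eff = k * temperature_factor(temp, params) * moisture_factor(theta, layer)
    return pool_n * -math.expm1(-k_eff)


def hydrolyze_urea(urea_n: float, temp: float, params: NRateParams) -> float:
    """Urea-to-ammonium conversion, first order with temperature response."""
    if urea_n < 0:
        raise ValueError("urea pool must be non-negative")
    flux = urea_n * params.k_hydrolysis * temperature_factor(temp, params)
    return min(flux, urea_n)


def volatilize(
    surface_nh4: float,
    days_since_application: float,
    water_applied_mm: float,
    incorporated: bool,
    params: NRateParams,
) -> float:
    """Ammonia loss from the surface ammonium pool, kg N ha-1 d-1.

    The daily loss fraction starts at ``volat_fraction`` on the
    application day and decays geometrically; water applied above a
    threshold (irrigation straight after broadcasting, or rain) washes
    urea into the soil and suppresses the loss; incorporated manure
    volatilises at a reduced fraction.
    """
    if surface_nh4 < 0:
        raise ValueError("surface ammonium must be non-negative")
    frac = params.volat_fraction * params.volat_decay ** max(0.0, days_since_application)
    if water_applied_mm >= params.volat_water_threshold_mm:
        frac *= params.volat_water_suppression
    if incorporated:
        frac *= params.volat_incorporated_factor
    return min(frac, 1.0) * surface_nh4


def nitrify(
    nh4_n: float, temp: float, theta: float, layer: SoilLayer, params: NRateParams
) -> float:
    """Ammonium-to-nitrate conversion, kg N ha-1 d-1."""
    if nh4_n < 0:
        raise ValueError("ammonium pool must be non-negative")
    flux = (
        nh4_n * params.k_nitrification
        * temperature_factor(temp, params) * moisture_factor(theta, layer)
    )
    return min(flux, nh4_n)


def denitrify(
    no3_n: float, theta: float, layer: SoilLayer, temp: float, params: NRateParams
) -> float:
    """Denitrification loss, zero below the WFPS threshold.

    Above the threshold the rate is first order in nitrate, scaled by a
    power of the excess water-filled pore space and the temperature
    factor; maximal at saturation.
    """
    if no3_n < 0:
        raise ValueError("nitrate pool must be non-negative")
    wfps = theta / layer.theta_s
    thr = params.wfps_threshold
    if wfps <= thr:
        return 0.0
    excess = min(1.0, (wfps - thr) / (1.0 - thr))
    flux = (
        no3_n * params.k_denitrification
        * excess ** params.denit_exponent
        * temperature_factor(temp, params)
    )
    return min(flux, no3_n)


def advect_nitrate(
    no3: np.ndarray,
    outflow_mm: np.ndarray,
    water_mm: np.ndarray,
    report_index: int | None = None,
) -> tuple[np.ndarray, float, float]:
    """Mixing-cell nitrate advection with the day's drainage cascade.

    ``outflow_mm[i]`` is the water leaving the bottom of layer ``i`` (as
    returned by :func:`vegrot.soilwater.redistribute`) and ``water_mm``
    the end-of-day stored water per layer. In each cell the inflowing
    mass mixes with the resident mass; the outflow carries the mixed
    concentration mass/(storage + outflow). Returns
    ``(new_no3, leached_at_report_plane, leached_at_bottom)`` where the
    reporting plane is the bottom of layer ``report_index`` (defaults to
    the deepest layer). Mass is conserved exactly.
    """
    no3 = np.asarray(no3, dtype=float)
    outflow_mm = np.asarray(outflow_mm, dtype=float)
    water_mm = np.asarray(water_mm, dtype=float)
    if (water_mm < 0).any():
        raise ValueError("negative layer water volume")
    if (outflow_mm < 0).any():
        raise ValueError("negative drainage flux")
    new = no3.copy()
    mass_in = 0.0
    leach_report = 0.0
    if report_index is None:
        report_index = len(no3) - 1
    for i in range(len(no3)):
        mass = new[i] + mass_in
        denom = water_mm[i] + outflow_mm[i]
        mass_out = 0.0
        if outflow_mm[i] > 0 and denom > 0:
            mass_out = mass * outflow_mm[i] / denom
        new[i] = mass - mass_out
        mass_in = mass_out
        if i == report_index:
            leach_report = mass_out
    return new, leach_report, mass_in


def plant_uptake_n(
    demand: float,
    mineral_by_layer: np.ndarray,
    root_fractions: np.ndarray,
    extractable_fraction: float,
) -> tuple[np.ndarray, float]:
    """Allocate crop N demand across rooted layers.

    Available N per layer is ``extractable_fraction`` of its mineral N
    (ammonium + nitrate) weighted by the root fraction; withdrawal is
    proportional to availability, total capped by supply.
    """
    if demand < 0:
        raise ValueError("N demand must be non-negative")
    mineral_by_layer = np.asarray(mineral_by_layer, dtype=float)
    root_fractions = np.asarray(root_fractions, dtype=float)
    avail = extractable_fraction * mineral_by_layer * (root_fractions > 0)
    take = proportional_allocation(demand, avail, avail)
    return take, float(take.sum())
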