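"""Layered tipping-bucket soil water balance.

The profile is a stack of layers, each with saturation, field capacity
and wilting point limits. Daily routing: incoming water is partitioned
into runoff and infiltration by the NRCS curve-number relation,
infiltration cascades down the profile (fill-and-spill toward field
capacity, with a first-order drainage coefficient emptying the
freely-drainable range between field capacity and saturation),
evaporation and transpiration are extracted from the top layer and the
rooted zone respectively, and water leaving the bottom of the deepest
layer is profile drainage. All depths are cm (positive downward), all
water fluxes mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SoilLayer", "SoilProfile", "SoilWaterState", "WaterFluxDay",
    "partition_runoff", "redistribute", "extract_et", "report_profile",
    "triangular_root_fractions",
]


@dataclass(frozen=True)
class SoilLayer:
    """One soil horizon with hydraulic limits (volumetric, cm3 cm-3)."""

    top: float  # cm
    bottom: float  # cm
    bulk_density: float  # g cm-3
    theta_s: float
    theta_fc: float
    theta_wp: float

    def __post_init__(self) -> None:
        if not self.bottom > self.top:
            raise ValueError(f"layer bottom {self.bottom} must exceed top {self.top}")
        if not 0 < self.theta_wp < self.theta_fc < self.theta_s < 1:
            raise ValueError(
                "require 0 < theta_wp < theta_fc < theta_s < 1, got "
                f"wp={self.theta_wp}, fc={self.theta_fc}, s={self.theta_s}"
            )

    @property
    def thickness(self) -> float:
        return self.bottom - self.top

    def mm(self, theta: float) -> float:
        """Water depth (mm) held at volumetric content ``theta``."""
        return theta * self.thickness * 10.0


@dataclass(frozen=True)
class SoilProfile:
    """Ordered, contiguous stack of :class:`SoilLayer`."""

    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        for above, below in zip(self.layers, self.layers[1:]):
            if not math.isclose(above.bottom, below.top, abs_tol=1e-9):
                raise ValueError("layers must be contiguous top-down")

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    @property
    def depth(self) -> float:
        return self.layers[-1].bottom

    def subdivide(self, max_thickness: float) -> "SoilProfile":
        """Split horizons into sub-layers no thicker than ``max_thickness`` cm."""
        out: list[SoilLayer] = []
        for lay in self.layers:
            n = max(1, math.ceil(lay.thickness / max_thickness - 1e-9))
            dz = lay.thickness / n
            for i in range(n):
                out.append(replace(lay, top=lay.top + i * dz, bottom=lay.top + (i + 1) * dz))
        return SoilProfile(tuple(out))


@dataclass
class SoilWaterState:
    """Per-layer volumetric water contents of a profile."""

    theta: np.ndarray  # cm3 cm-3, one entry per layer

    def copy(self) -> "SoilWaterState":
        return SoilWaterState(self.theta.copy())

    def storage_mm(self, profile: SoilProfile, to_depth: float | None = None) -> float:
        """Stored water (mm), optionally only above ``to_depth`` cm."""
        total = 0.0
        for th, lay in zip(self.theta, profile):
            if to_depth is not None and lay.top >= to_depth:
                break
            frac = 1.0
            if to_depth is not None and lay.bottom > to_depth:
                frac = (to_depth - lay.top) / lay.thickness
            total += lay.mm(th) * frac
        return total


@dataclass
class WaterFluxDay:
    """One day's water ledger entries, all mm."""

    rain: float = 0.0
    irrigation: float = 0.0
    runoff: float = 0.0
    infiltration: float = 0.0
    soil_evap: float = 0.0
    transpiration: float = 0.0
    drainage_bottom: float = 0.0
    drainage_report: float = 0.0  # past the reporting plane (default 90 cm)

    @property
    def et(self) -> float:
        return self.soil_evap + self.transpiration


def partition_runoff(water_in: float, curve_number: float) -> tuple[float, float]:
    """NRCS curve-number runoff with initial abstraction 0.2 S.

    Returns ``(runoff, infiltration)`` in mm, with
    ``runoff + infiltration == water_in``. ``curve_number`` of 100 makes
    all water run off; low numbers infiltrate nearly everything.
    """
    if water_in < 0:
        raise ValueError("water_in must be non-negative")
    if not 0 < curve_number <= 100:
        raise ValueError(f"curve number {curve_number} outside (0, 100]")
    s = 25400.0 / curve_number - 254.0  # potential retention, mm
    ia = 0.2 * s
    if water_in <= ia:
        runoff = 0.0
    else:
        runoff = (water_in - ia) ** 2 / (water_in - ia + s)
    return runoff, water_in - runoff


def redistribute(
    state: SoilWaterState,
    infiltration: float,
    profile: SoilProfile,
    drain_coeff: float = 0.5,
) -> tuple[SoilWaterState, np.ndarray]:
    """Cascade infiltrating water down the profile.

    Each layer first passes on any water above saturation immediately,
    then releases a fraction ``drain_coeff`` per day of the water held
    between field capacity and saturation. Water entering a layer fills
    it toward (at most) saturation; the overflow joins that layer's
    outflow. Returns the new state and the downward flux (mm) leaving
    the bottom of each layer; the last entry is profile drainage.
    """
    if infiltration < 0:
        raise ValueError("infiltration must be non-negative")
    if not 0 <= drain_coeff <= 1:
        raise ValueError("drain_coeff must lie in [0, 1]")
    theta = state.theta.copy()
    out = np.zeros(len(profile))
    flux_in = infiltration
    for i, lay in enumerate(profile):
        water = lay.mm(theta[i]) + flux_in
        cap_sat = lay.mm(lay.theta_s)
        cap_fc = lay.mm(lay.theta_fc)
        overflow = max(0.0, water - cap_sat)
        water -= overflow
        drainable = max(0.0, water - cap_fc)
        drained = drain_coeff * drainable
        water -= drained
        out[i] = overflow + drained
        theta[i] = water / (lay.thickness * 10.0)
        flux_in = out[i]
    return SoilWaterState(theta), out


def triangular_root_fractions(profile: SoilProfile, root_depth: float) -> np.ndarray:
    """Per-layer root fractions for a triangular density profile.

    Root density declines linearly from the surface to zero at
    ``root_depth`` cm; fractions integrate the density over each layer
    and sum to 1 (all zeros if ``root_depth`` is 0).
    """
    fr = np.zeros(len(profile))
    if root_depth <= 0:
        return fr
    for i, lay in enumerate(profile):
        z0 = min(lay.top, root_depth)
        z1 = min(lay.bottom, root_depth)
        if z1 <= z0:
            continue
        # integral of (1 - z/rd) dz over [z0, z1], normalised by rd/2
        fr[i] = ((z1 - z0) - (z1**2 - z0**2) / (2.0 * root_depth)) / (root_depth / 2.0)
    return fr


def extract_et(
    state: SoilWaterState,
    soil_evap_demand: float,
    transp_demand: float,
    root_depth: float,
    profile: SoilProfile,
    air_dry_fraction: float = 0.5,
) -> tuple[SoilWaterState, float, float]:
    """Withdraw soil evaporation and transpiration from the profile.

    Evaporation comes from the top layer only, never drawing below the
    air-dry limit (``air_dry_fraction`` x wilting point). Transpiration
    is taken from rooted layers in proportion to root fraction times
    plant-available water (above wilting point), capped by supply.
    Returns ``(new_state, evap_actual, transp_actual)``.
    """
    if soil_evap_demand < 0 or transp_demand < 0:
        raise ValueError("ET demands must be non-negative")
    theta = state.theta.copy()
    top = profile.layers[0]
    air_dry = air_dry_fraction * top.theta_wp
    evap_avail = max(0.0, top.mm(theta[0]) - top.mm(air_dry))
    evap = min(soil_evap_demand, evap_avail)
    theta[0] -= evap / (top.thickness * 10.0)

    fr = triangular_root_fractions(profile, root_depth)
    avail = np.array([
        max(0.0, lay.mm(th) - lay.mm(lay.theta_wp))
        for th, lay in zip(theta, profile)
    ])
    weight = fr * avail
    take = proportional_allocation(transp_demand, weight, avail)
    transp = float(take.sum())
    for i, lay in enumerate(profile):
        theta[i] -= take[i] / (lay.thickness * 10.0)
    return SoilWaterState(theta), evap, transp


def proportional_allocation(
    demand: float, weight: np.ndarray, cap: np.ndarray
) -> np.ndarray:
    """Split ``demand`` across sources proportionally to ``weight``.

    Each source ``i`` receives ``min(lam * weight_i, cap_i)`` for the
    scaling ``lam`` at which the allocations sum to
    ``min(demand, sum of reachable caps)``: sources that hit their cap
    free their share for the rest. Solved exactly by iterating the
    proportional rule over uncapped sources (fixed point in at most
    ``len(weight)`` rounds).
    """
    weight = np.asarray(weight, dtype=float)
    cap = np.asarray(cap, dtype=float)
    take = np.zeros_like(cap)
    if demand <= 0:
        return take
    active = weight > 0
    remaining = min(demand, cap[active].sum())
    while remaining > 1e-15 and active.any():
        share = remaining * weight * active / weight[active].sum()
        hit = active & (share >= cap - take)
        if not hit.any():
            take += share
            break
        take[hit] = cap[hit]
        active &= ~hit
        remaining = min(demand - take.sum(), cap[active].sum()) if active.any() else 0.0
    return take


def report_profile(
    state: SoilWaterState,
    profile: SoilProfile,
    reporting_layers: Sequence[tuple[float, float]],
) -> list[float]:
    """Thickness-weighted mean water content over reporting intervals.

    ``reporting_layers`` are (top, bottom) depth intervals in cm; each
    must lie inside the simulated domain.
    """
    out = []
    for top, bottom in reporting_layers:
        if top < profile.layers[0].top - 1e-9 or bottom > profile.depth + 1e-9:
            raise ValueError(f"reporting interval ({top}, {bottom}) outside domain")
        if bottom <= top:
            raise ValueError("reporting interval must have bottom > top")
        weighted = 0.0
        for th, lay in zip(state.theta, profile):
            overlap = max(0.0, min(bottom, lay.bottom) - max(top, lay.top))
            weighted += th * overlap
        out.append(weighted / (bottom - top))
    return out
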