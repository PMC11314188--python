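"""Daily rotation simulator: water, nitrogen and crop growth.

One run walks a daily loop over a weather series and a management event
schedule: reference ET and crop demand, curve-number runoff,
tipping-bucket redistribution with drainage, surface-pool N chemistry
(hydrolysis, volatilisation, two-pool mineralisation, nitrification,
denitrification), mixing-cell nitrate advection, and crop uptake and
growth. Crop state resets at each sowing; soil water and N state carry
across seasons, which is what lets a following crop scavenge residual
mineral N. Seasonal ledgers accumulate between sowing and harvest and
are reported against a 0.9 m plane even though the simulated column
extends to 1.2 m.

Every simulated day the water and N books are closed: the residuals of

    rain + irrigation = runoff + dStorage + Esoil + T + drainage(bottom)
    fert + manure + Nirr = dPools + uptake + volat + denit + leach(bottom)

are recorded and should vanish to numerical precision.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import crop as cropmod
from . import soilnitrogen as nmod
from . import soilwater as swmod
from .accounting import SeasonBalance, combine_balance, season_n_balance, \
    season_water_balance, aggregate_annual
from .crop import CropParams, CropState, DEFAULT_CROPS
from .io import ManagementEvent
from .soilnitrogen import NPoolState, NRateParams
from .soilwater import SoilLayer, SoilProfile, SoilWaterState
from .study_tables import SOIL_PROFILE
from .weather import DailyWeather, Site, crop_et_demand, crop_kc, reference_et

__all__ = ["SimParams", "IrrigationRule", "RunConfig", "RotationResult",
           "run_rotation", "default_profile", "default_config",
           "REPORT_INTERVALS"]

#: Water-content reporting intervals (cm), matching the TDR depths.
REPORT_INTERVALS = ((0, 15), (15, 30), (30, 60), (60, 90), (90, 120))


@dataclass
class SimParams:
    """Scalar knobs of the daily loop (all calibratable)."""

    curve_number: float = 75.0      # NRCS CN for rainfall
    drain_coeff: float = 0.5        # per-day drainable-range release
    air_dry_fraction: float = 0.5   # top-layer evaporation floor / theta_wp
    soil_kc: float = 0.6            # bare / under-canopy evaporation coeff
    dm_full_cover: float = 1.5      # t ha-1 DM at canopy closure
    irrigation_no3_mg_l: float = 3.9  # nitrate in irrigation water
    reporting_plane: float = 90.0   # cm; drainage/leaching ledger depth
    manure_tan_fraction: float = 0.3  # ammoniacal share of manure N
    manure_incorporation_depth: float = 20.0  # cm
    n_rates: NRateParams = field(default_factory=NRateParams)


@dataclass(frozen=True)
class IrrigationRule:
    """Sensor-triggered irrigation: refill when the control zone dries.

    When the mean water content over ``control_depth`` falls below
    ``trigger`` x field capacity, irrigate back up to ``refill`` x field
    capacity. Mimics TDR-scheduled micro-sprinkler management.
    """

    trigger: float = 0.5
    refill: float = 0.8
    control_depth: float = 30.0  # cm


@dataclass
class RunConfig:
    """Everything one rotation run needs."""

    site: Site
    weather: Sequence[DailyWeather]
    events: Sequence[ManagementEvent]
    profile: SoilProfile
    crops: Mapping[str, CropParams] = field(default_factory=lambda: dict(DEFAULT_CROPS))
    params: SimParams = field(default_factory=SimParams)
    irrigation_rule: IrrigationRule | None = None
    initial_theta: np.ndarray | None = None      # default: field capacity
    initial_no3_total: float = 60.0              # kg N ha-1 over the column
    initial_nh4_total: float = 10.0
    #: organic (humus) N concentration per horizon of the 4-horizon
    #: profile, g N per kg soil, surface first
    humus_n_g_kg: tuple[float, ...] = (1.2, 0.6, 0.4, 0.3)
    treatment: str = ""

    def __post_init__(self) -> None:
        dates = [w.date for w in self.weather]
        if len(dates) != len(set(dates)):
            raise ValueError("duplicate dates in weather series")
        have = set(dates)
        for e in self.events:
            if e.date not in have:
                raise ValueError(
                    f"management event on {e.date} outside the weather record")


def default_profile(sublayer_cm: float = 15.0) -> SoilProfile:
    """The experimental soil column (4 horizons to 120 cm), subdivided."""
    layers = tuple(
        SoilLayer(top=r[0], bottom=r[1], bulk_density=r[6],
                  theta_fc=r[7], theta_wp=r[8], theta_s=r[9])
        for r in SOIL_PROFILE
    )
    return SoilProfile(layers).subdivide(sublayer_cm)


def _initial_pools(config: RunConfig) -> NPoolState:
    profile = config.profile
    n = len(profile)
    pools = NPoolState.zeros(n)
    thick = np.array([l.thickness for l in profile])
    # mineral N spread over the column proportional to thickness
    pools.no3 += config.initial_no3_total * thick / thick.sum()
    pools.nh4 += config.initial_nh4_total * thick / thick.sum()
    # humus N from per-horizon concentration x bulk density x thickness
    horizons = [(r[0], r[1]) for r in SOIL_PROFILE]
    for i, lay in enumerate(profile):
        for (top, bottom), conc in zip(horizons, config.humus_n_g_kg):
            overlap = max(0.0, min(lay.bottom, bottom) - max(lay.top, top))
            pools.humus[i] += conc * lay.bulk_density * overlap * 100.0
    return pools


def _report_index(profile: SoilProfile, plane: float) -> int:
    for i, lay in enumerate(profile):
        if abs(lay.bottom - plane) < 1e-6:
            return i
    raise ValueError(f"no layer boundary at the {plane} cm reporting plane")


@dataclass
class _SeasonAccum:
    crop: str = ""
    year: int = 0
    sow: _dt.date | None = None
    harvest: _dt.date | None = None
    rain: float = 0.0
    irrigation: float = 0.0
    et: float = 0.0
    drainage: float = 0.0
    manure: float = 0.0
    fert: float = 0.0
    nirr: float = 0.0
    nnet: float = 0.0
    uptake: float = 0.0
    gaseous: float = 0.0
    leached: float = 0.0
    start_mineral_n: float = 0.0


@dataclass
class RotationResult:
    """Simulation output: per-day table, per-season and annual ledgers."""

    daily: pd.DataFrame
    seasons: list[SeasonBalance]
    annual: list[SeasonBalance]
    season_meta: list[dict]

    def season(self, year: int, crop: str) -> SeasonBalance:
        for s in self.seasons:
            if s.year == year and s.crop == crop:
                return s
        raise KeyError((year, crop))


def run_rotation(config: RunConfig) -> RotationResult:
    """Execute the daily loop over the configured weather and schedule."""
    profile = config.profile
    p = config.params
    nr = p.n_rates
    rep_idx = _report_index(profile, p.reporting_plane)
    thickness_mm = np.array([l.thickness * 10.0 for l in profile])

    theta0 = (np.array([l.theta_fc for l in profile], dtype=float)
              if config.initial_theta is None
              else np.asarray(config.initial_theta, dtype=float).copy())
    wstate = SoilWaterState(theta0)
    pools = _initial_pools(config)

    events_by_date: dict[_dt.date, list[ManagementEvent]] = {}
    order = {"sowing": 0, "manure": 1, "urea": 2, "irrigation": 3, "harvest": 4}
    for e in sorted(config.events, key=lambda e: (e.date, order[e.kind])):
        events_by_date.setdefault(e.date, []).append(e)

    crop_state: CropState | None = None
    crop_params: CropParams | None = None
    season_len = 1
    days_since_app = 1e9
    app_incorporated = False

    seasons: list[SeasonBalance] = []
    season_meta: list[dict] = []
    acc: _SeasonAccum | None = None
    rows = []

    report_intervals = [iv for iv in REPORT_INTERVALS if iv[1] <= profile.depth]

    for day in config.weather:
        date = day.date
        rain = day.rain
        irrigation = 0.0
        fert_applied = 0.0
        manure_applied = 0.0
        nirr = 0.0
        harvest_record = None

        pools_before = pools.total()
        storage_before = wstate.storage_mm(profile)

        # --- management events -------------------------------------------
        for ev in events_by_date.get(date, ()):
            if ev.kind == "sowing":
                crop_params = config.crops[ev.crop]
                crop_state = CropState(
                    days_since_sowing=0, dry_matter=crop_params.initial_dm,
                    plant_n=crop_params.initial_dm * 10.0 * crop_params.seedling_n_pct,
                    root_depth=5.0)
                harvest_dates = [e2.date for e2 in config.events
                                 if e2.kind == "harvest" and e2.crop == ev.crop
                                 and e2.date > date]
                season_len = max(1, ((min(harvest_dates) - date).days
                                     if harvest_dates else 60))
                acc = _SeasonAccum(crop=ev.crop, year=date.year, sow=date,
                                   start_mineral_n=float(pools.mineral.sum()))
            elif ev.kind == "harvest":
                if crop_state is not None and crop_params is not None:
                    harvest_record = (ev.crop,
                                      cropmod.fresh_yield(crop_state, crop_params))
                crop_state = None
                crop_params = None
            elif ev.kind == "manure":
                manure_applied += ev.amount
                tan = p.manure_tan_fraction * ev.amount
                org = ev.amount - tan
                pools.nh4[0] += tan
                depth = p.manure_incorporation_depth if ev.incorporated else \
                    profile.layers[0].thickness
                for i, lay in enumerate(profile):
                    overlap = max(0.0, min(lay.bottom, depth) - lay.top)
                    pools.manure_organic[i] += org * overlap / depth
                days_since_app = 0.0
                app_incorporated = ev.incorporated
            elif ev.kind == "urea":
                fert_applied += ev.amount
                pools.urea[0] += ev.amount
                days_since_app = 0.0
                app_incorporated = False
            elif ev.kind == "irrigation":
                irrigation += ev.amount

        # --- rule-based irrigation ---------------------------------------
        if (config.irrigation_rule is not None and crop_state is not None
                and irrigation == 0.0):
            rule = config.irrigation_rule
            zone = [(i, lay) for i, lay in enumerate(profile)
                    if lay.top < rule.control_depth]
            zmm = sum(lay.thickness * 10.0 for _, lay in zone)
            held = sum(wstate.theta[i] * lay.thickness * 10.0 for i, lay in zone)
            fc = sum(lay.theta_fc * lay.thickness * 10.0 for _, lay in zone)
            if held < rule.trigger * fc:
                irrigation = max(0.0, rule.refill * fc - held)
        if irrigation > 0:
            nirr = irrigation * p.irrigation_no3_mg_l * 0.01
            pools.no3[0] += nirr

        # --- evapotranspiration demand -----------------------------------
        et0 = reference_et(day, config.site)
        if crop_state is not None and crop_params is not None:
            fseason = min(1.0, crop_state.days_since_sowing / season_len)
            kc = crop_kc(fseason, crop_params.kc)
            etc = crop_et_demand(et0, kc)
            cover = min(1.0, crop_state.dry_matter / p.dm_full_cover)
            transp_demand = cover * etc
            evap_demand = (1.0 - cover) * p.soil_kc * et0
        else:
            transp_demand = 0.0
            evap_demand = p.soil_kc * et0

        # --- water routing ------------------------------------------------
        runoff, infil_rain = swmod.partition_runoff(rain, p.curve_number)
        infiltration = infil_rain + irrigation
        wstate, outflow = swmod.redistribute(
            wstate, infiltration, profile, p.drain_coeff)
        drainage_report = float(outflow[rep_idx])
        drainage_bottom = float(outflow[-1])
        root_depth = crop_state.root_depth if crop_state is not None else 0.0
        wstate, evap, transp = swmod.extract_et(
            wstate, evap_demand, transp_demand, root_depth, profile,
            p.air_dry_fraction)
        water_stress = 1.0 if transp_demand <= 0 else min(1.0, transp / transp_demand)

        # --- nitrogen transformations --------------------------------------
        tmean = day.tmean
        hyd = nmod.hydrolyze_urea(pools.urea[0], tmean, nr)
        pools.urea[0] -= hyd
        pools.nh4[0] += hyd
        vol = nmod.volatilize(pools.nh4[0], days_since_app, rain + irrigation,
                              app_incorporated, nr)
        pools.nh4[0] -= vol

        humus_net = 0.0
        manure_min = 0.0
        denit = 0.0
        for i, lay in enumerate(profile):
            th = wstate.theta[i]
            rh_ = nmod.mineralize(pools.humus[i], nr.k_humus, tmean, th, lay, nr)
            rh_net = rh_ * (1.0 - nr.immobilization)
            pools.humus[i] -= rh_net
            pools.nh4[i] += rh_net
            humus_net += rh_net
            rm_ = nmod.mineralize(pools.manure_organic[i], nr.k_manure, tmean,
                                  th, lay, nr)
            pools.manure_organic[i] -= rm_
            pools.nh4[i] += rm_
            manure_min += rm_
            nit = nmod.nitrify(pools.nh4[i], tmean, th, lay, nr)
            pools.nh4[i] -= nit
            pools.no3[i] += nit
            dn = nmod.denitrify(pools.no3[i], th, lay, tmean, nr)
            pools.no3[i] -= dn
            denit += dn

        water_mm = wstate.theta * thickness_mm
        pools.no3, leach_report, leach_bottom = nmod.advect_nitrate(
            pools.no3, outflow, water_mm, rep_idx)

        # --- crop growth and N uptake --------------------------------------
        uptake = 0.0
        if crop_state is not None and crop_params is not None:
            nstress = cropmod.n_stress(crop_state, crop_params)
            nxt = cropmod.grow_daily(crop_state, crop_params, water_stress,
                                     nstress, tmean)
            demand = cropmod.n_demand(crop_state, crop_params, nxt.dry_matter)
            fr = swmod.triangular_root_fractions(profile, nxt.root_depth)
            mineral = pools.nh4 + pools.no3
            take, uptake = nmod.plant_uptake_n(
                demand, mineral, fr, nr.uptake_extractable_fraction)
            for i in range(len(profile)):
                if take[i] <= 0 or mineral[i] <= 0:
                    continue
                share_no3 = pools.no3[i] / mineral[i]
                pools.no3[i] -= take[i] * share_no3
                pools.nh4[i] -= take[i] * (1.0 - share_no3)
            nxt.plant_n = crop_state.plant_n + uptake
            crop_state = nxt

        days_since_app += 1.0

        # --- closure ---------------------------------------------------------
        storage_after = wstate.storage_mm(profile)
        water_residual = (rain + irrigation) - (
            runoff + evap + transp + drainage_bottom
            + (storage_after - storage_before))
        pools_after = pools.total()
        n_residual = (fert_applied + manure_applied + nirr) - (
            vol + denit + leach_bottom + uptake + (pools_after - pools_before))

        # --- season ledger ---------------------------------------------------
        in_season = acc is not None and acc.harvest is None
        if in_season:
            acc.rain += rain
            acc.irrigation += irrigation
            acc.et += evap + transp
            acc.drainage += drainage_report
            acc.manure += manure_applied
            acc.fert += fert_applied
            acc.nirr += nirr
            acc.nnet += humus_net
            acc.uptake += uptake
            acc.gaseous += vol + denit
            acc.leached += leach_report
        if harvest_record is not None and acc is not None:
            acc.harvest = date
            crop_name, y = harvest_record
            water = season_water_balance(
                acc.rain, acc.irrigation, acc.et, acc.drainage, y,
                treatment=config.treatment, crop=crop_name, year=acc.year)
            nitro = season_n_balance(
                acc.manure, acc.fert, acc.nirr, acc.nnet, acc.uptake,
                acc.gaseous, acc.leached, y, treatment=config.treatment,
                crop=crop_name, year=acc.year)
            seasons.append(combine_balance(water, nitro))
            season_meta.append({
                "crop": crop_name, "year": acc.year, "sow": acc.sow,
                "harvest": date, "yield_fresh": y,
                "start_mineral_n": acc.start_mineral_n,
                "end_mineral_n": float(pools.mineral.sum()),
            })
            acc = None

        pools.check_nonnegative()
        theta_report = swmod.report_profile(wstate, profile, report_intervals)

        row = {
            "date": date, "et0": et0, "rain": rain, "irrigation": irrigation,
            "runoff": runoff, "infiltration": infiltration,
            "soil_evap": evap, "transpiration": transp, "et": evap + transp,
            "drainage_90": drainage_report, "drainage_bottom": drainage_bottom,
            "storage_mm": storage_after,
            "fert_n": fert_applied, "manure_n": manure_applied, "nirr": nirr,
            "hydrolysis": hyd, "volatilization": vol, "denitrification": denit,
            "net_mineralization": humus_net, "manure_mineralization": manure_min,
            "leach_90": leach_report, "leach_bottom": leach_bottom,
            "uptake_n": uptake,
            "mineral_n_total": float(pools.mineral.sum()),
            "mineral_n_0_90": float(sum(
                (pools.nh4[i] + pools.no3[i])
                * (min(lay.bottom, p.reporting_plane) - lay.top) / lay.thickness
                for i, lay in enumerate(profile) if lay.top < p.reporting_plane)),
            "water_residual": water_residual, "n_residual": n_residual,
            "crop": acc.crop if in_season and acc is not None else "",
            "dm": crop_state.dry_matter if crop_state is not None else 0.0,
            "plant_n": crop_state.plant_n if crop_state is not None else 0.0,
            "root_depth": crop_state.root_depth if crop_state is not None else 0.0,
        }
        for (top, bottom), th in zip(report_intervals, theta_report):
            row[f"theta_{top}_{bottom}"] = th
        iv = None
        for j, (top, bottom) in enumerate(report_intervals):
            if (top, bottom) == (60, 90):
                iv = (top, bottom)
        if iv is not None:
            mass = sum(pools.no3[i] for i, lay in enumerate(profile)
                       if lay.top >= 60 and lay.bottom <= 90)
            water = sum(wstate.theta[i] * lay.thickness * 10.0
                        for i, lay in enumerate(profile)
                        if lay.top >= 60 and lay.bottom <= 90)
            row["no3_conc_60_90"] = mass * 100.0 / water if water > 0 else 0.0
        rows.append(row)

    daily = pd.DataFrame(rows).set_index("date")
    annual = []
    for year in sorted({s.year for s in seasons}):
        annual.append(aggregate_annual([s for s in seasons if s.year == year]))
    return RotationResult(daily=daily, seasons=seasons, annual=annual,
                          season_meta=season_meta)


def default_config(
    treatment: str, year: int, seed: int = 0,
    rule_based_irrigation: bool = False,
) -> RunConfig:
    """A ready-to-run scenario for one treatment-year.

    Generates weather and a management schedule from the reported
    seasonal totals and the Beijing climate description; the soil is
    the experimental profile subdivided to 15 cm.
    """
    from .synthetic import default_weather_config, generate_management, \
        generate_weather

    wconf = default_weather_config(year)
    # independent sub-streams for weather and management
    weather = generate_weather(wconf, seed=seed * 2 + 1)
    events = generate_management(treatment, year, seed=seed * 2 + 2,
                                 rule_based_irrigation=rule_based_irrigation)
    return RunConfig(
        site=Site(latitude=39.9, altitude=50.0),
        weather=weather, events=events, profile=default_profile(),
        irrigation_rule=IrrigationRule() if rule_based_irrigation else None,
        treatment=treatment,
    )
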