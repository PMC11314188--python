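"""Self-consistency calibration exercise.

Since the original field calibration data are unpublished, the harness
closes the loop on the simulator itself: it runs one cauliflower season
at known ("true") parameter values, samples pseudo-observations of the
layer water contents and the plant N trajectory, then asks the staged
search to recover the generating values starting from the package
defaults. With zero observation noise the truth is the global optimum
(objective 0) and should be recovered to within one grid step; at the
default noise level recovery within ~10 % is expected.

The calibration follows the conventional staging: water-side parameters
first (the mid-season crop coefficient, which drives transpiration and
hence the water-content trajectory), then the crop N parameters (the
dilution-curve coefficient and the luxury-uptake ceiling, which drive
the plant N trajectory). The fertiliser supply in the exercise is kept
moderate so that late-season N limitation separates the dilution
coefficient (visible in growth under stress) from the luxury ceiling
(visible in early uptake).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace as _dc_replace
from typing import Mapping

import numpy as np

from .calibrate import CalibrationStage, calibrate, weighted_rmse_objective
from .crop import DEFAULT_CROPS
from .io import ManagementEvent
from .simulate import RunConfig, SimParams, default_profile, run_rotation
from .synthetic import RainWindow, WeatherGenConfig, generate_weather
from .weather import Site

__all__ = ["RecoveryOutcome", "recovery_grids", "run_recovery",
           "TRUE_PARAMS", "season_scenario", "simulate_for_params"]

#: Generating values for the recovery exercise; all lie on the search
#: grids and differ from the package defaults.
TRUE_PARAMS: dict[str, float] = {
    "kc_mid": 1.15,
    "dilution_a": 4.4,
    "luxury_l": 1.25,
}


def recovery_grids() -> list[CalibrationStage]:
    """The staged grids (water stage first, then crop N)."""
    return [
        CalibrationStage("water", {
            "kc_mid": (0.85, 0.95, 1.05, 1.15, 1.25),
        }),
        CalibrationStage("crop_n", {
            "dilution_a": (3.2, 3.6, 4.0, 4.4, 4.8),
            "luxury_l": (1.05, 1.15, 1.25, 1.35),
        }),
    ]


def season_scenario(seed: int) -> RunConfig:
    """One ~70-day cauliflower season with moderate N supply."""
    start = _dt.date(2000, 3, 30)
    sow = _dt.date(2000, 4, 3)
    harvest = _dt.date(2000, 6, 6)
    end = _dt.date(2000, 6, 10)
    wconf = WeatherGenConfig(
        start=start, end=end,
        rain_windows=(RainWindow(sow, harvest, 45.1, 5, 9),))
    weather = generate_weather(wconf, seed=seed)
    events = [
        ManagementEvent(date=sow, kind="sowing", crop="cauliflower"),
        ManagementEvent(date=sow, kind="urea", amount=60.0),
        ManagementEvent(date=_dt.date(2000, 4, 28), kind="urea", amount=60.0),
        ManagementEvent(date=harvest, kind="harvest", crop="cauliflower"),
    ]
    # regular irrigation so the water signal reflects the crop coefficient
    for day in range(2, (harvest - sow).days, 7):
        events.append(ManagementEvent(
            date=sow + _dt.timedelta(days=day), kind="irrigation", amount=30.0))
    return RunConfig(site=Site(latitude=39.9, altitude=50.0), weather=weather,
                     events=events, profile=default_profile(),
                     treatment="recovery")


def simulate_for_params(
    base: RunConfig, params: Mapping[str, float]
) -> dict[str, np.ndarray]:
    """Run the scenario at given parameter values; return observables."""
    cau = DEFAULT_CROPS["cauliflower"]
    kc = _dc_replace(cau.kc, kc_mid=float(params.get("kc_mid", cau.kc.kc_mid)))
    crop = _dc_replace(
        cau, kc=kc,
        dilution_a=float(params.get("dilution_a", cau.dilution_a)),
        luxury_l=float(params.get("luxury_l", cau.luxury_l)))
    config = _dc_replace(base, crops={**DEFAULT_CROPS, "cauliflower": crop})
    result = run_rotation(config)
    d = result.daily
    return {
        "theta_0_15": d["theta_0_15"].to_numpy(),
        "theta_15_30": d["theta_15_30"].to_numpy(),
        "plant_n": d["plant_n"].to_numpy(),
        "dm": d["dm"].to_numpy(),
    }


@dataclass
class RecoveryOutcome:
    """Result of one self-consistency recovery run."""

    true_params: dict[str, float]
    recovered: dict[str, float]
    objective: float
    rejected: int

    def relative_errors(self) -> dict[str, float]:
        return {k: abs(self.recovered[k] - v) / abs(v)
                for k, v in self.true_params.items()}


def run_recovery(
    seed: int = 0,
    noise_sd_theta: float = 0.0,
    noise_sd_plant_n: float = 0.0,
) -> RecoveryOutcome:
    """Generate truth observations and run the staged search.

    ``noise_sd_theta`` is the Gaussian sd added to the water-content
    series (cm3 cm-3) and ``noise_sd_plant_n`` the sd added to the
    plant N series (kg N ha-1); zero noise makes the truth the exact
    global optimum.
    """
    base = season_scenario(seed)
    truth = simulate_for_params(base, TRUE_PARAMS)
    rng = np.random.default_rng(seed + 1)
    obs = {}
    for var, series in truth.items():
        noisy = series.astype(float).copy()
        if var.startswith("theta_") and noise_sd_theta > 0:
            noisy = np.clip(noisy + rng.normal(0, noise_sd_theta, noisy.size),
                            0.0, 0.55)
        elif var == "plant_n" and noise_sd_plant_n > 0:
            noisy = np.maximum(0.0, noisy + rng.normal(0, noise_sd_plant_n,
                                                       noisy.size))
        obs[var] = noisy

    # weights put the water channel and the N channel on similar scales
    objective = weighted_rmse_objective(
        lambda p: simulate_for_params(base, p), obs,
        weights={"theta_0_15": 50.0, "theta_15_30": 50.0,
                 "plant_n": 0.02, "dm": 1.0})
    defaults = {
        "kc_mid": DEFAULT_CROPS["cauliflower"].kc.kc_mid,
        "dilution_a": DEFAULT_CROPS["cauliflower"].dilution_a,
        "luxury_l": DEFAULT_CROPS["cauliflower"].luxury_l,
    }
    result = calibrate(objective, recovery_grids(), defaults)
    return RecoveryOutcome(true_params=dict(TRUE_PARAMS),
                           recovered=result.params,
                           objective=result.objective,
                           rejected=result.rejected)
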