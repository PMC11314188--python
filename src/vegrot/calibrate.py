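"""Staged grid / coordinate-descent calibration harness.

Field calibrations of this model family are traditionally done by trial
and error against observations in a fixed order: soil-water parameters
first, then N-transformation constants, then crop parameters. This
module replaces that manual loop with a deterministic staged grid
search: each stage owns a set of named parameters with candidate grids,
searched exhaustively over their Cartesian product while the other
stages stay frozen. The objective is typically a weighted RMSE over the
observed variables. Given the same stages, grids and objective the
result is exactly reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .evaluate import rmse

__all__ = ["CalibrationStage", "CalibrationResult", "calibrate",
           "weighted_rmse_objective"]


@dataclass(frozen=True)
class CalibrationStage:
    """One calibration stage: named parameter grids searched together."""

    name: str
    grids: Mapping[str, Sequence[float]]


@dataclass
class CalibrationResult:
    """Outcome of a staged search."""

    params: dict[str, float]
    objective: float
    trace: list[tuple[str, dict[str, float], float]] = field(default_factory=list)
    rejected: int = 0  # candidates with non-finite objective


def weighted_rmse_objective(
    run: Callable[[dict[str, float]], Mapping[str, Sequence[float]]],
    observations: Mapping[str, Sequence[float]],
    weights: Mapping[str, float] | None = None,
) -> Callable[[dict[str, float]], float]:
    """Build an objective: weighted sum of per-variable RMSEs.

    ``run(params)`` must return simulated series keyed like
    ``observations``. Weights default to 1; scale them to balance the
    units of dissimilar variables.
    """
    weights = dict(weights or {})

    def objective(params: dict[str, float]) -> float:
        sim = run(params)
        total = 0.0
        for var, obs in observations.items():
            total += weights.get(var, 1.0) * rmse(sim[var], obs)
        return total

    return objective


def calibrate(
    objective: Callable[[dict[str, float]], float],
    stages: Sequence[CalibrationStage],
    defaults: Mapping[str, float],
) -> CalibrationResult:
    """Run the staged grid search.

    Starts from ``defaults``. Within a stage the full Cartesian product
    of that stage's parameter grids is evaluated (parameters of earlier
    stages stay frozen at their incumbent values, later stages at the
    defaults), so that parameters with correlated effects inside one
    stage cannot trap the search in an off-axis local minimum.
    Candidates whose objective is non-finite are rejected (counted in
    ``rejected``). With empty ``stages`` the defaults are returned
    unchanged, with their objective evaluated. The search contract is
    that the returned objective never exceeds the objective at the
    defaults.
    """
    params = dict(defaults)
    best = objective(dict(params))
    if not math.isfinite(best):
        raise ValueError("objective is non-finite at the default parameters")
    result = CalibrationResult(params=params, objective=best)
    result.trace.append(("defaults", dict(params), best))
    for stage in stages:
        names = list(stage.grids)
        for values in itertools.product(*(stage.grids[n] for n in names)):
            trial = dict(params)
            trial.update(zip(names, values))
            if trial == params:
                continue
            score = objective(trial)
            if not math.isfinite(score):
                result.rejected += 1
                continue
            result.trace.append((stage.name, dict(trial), score))
            if score < best:
                best = score
                params = trial
    result.params = dict(params)
    result.objective = best
    return result
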