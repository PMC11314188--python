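"""Budget-based optimal N fertiliser recommendation (Expert-N style).

The recommended dose balances the expected crop uptake, a target
post-harvest residual and an empirical seasonal loss against the
mineral N already in the root zone and the mineralisation credits:

    N_opt = N_upt + N_res + N_loss - N_ini - N_hum - N_root

with the loss term estimated from the farmer-practice rate:

    N_loss = N_input x 0.019 x growing-season length in weeks.

All quantities in kg N ha-1. A negative budget clamps to zero (no
fertiliser), which does occur for short, well-supplied seasons.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RecommendationInputs", "n_loss_estimate", "recommend_n", "reduced_rate",
           "LOSS_RATE_PER_WEEK"]

#: Empirical weekly loss coefficient on the farmer-practice rate.
LOSS_RATE_PER_WEEK = 0.019


@dataclass(frozen=True)
class RecommendationInputs:
    """Inputs to the fertiliser budget (kg N ha-1; season in weeks)."""

    n_upt: float            # expected crop uptake over the season
    n_res: float            # target root-zone mineral N after harvest
    n_ini: float            # root-zone mineral N at season start
    n_hum: float            # seasonal soil organic N mineralisation
    n_root: float           # crop-residue mineralisation credit
    n_input_farmer: float   # farmer-practice N rate (for the loss term)
    season_weeks: float

    def __post_init__(self) -> None:
        for name in ("n_upt", "n_res", "n_ini", "n_hum", "n_root", "n_input_farmer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.season_weeks <= 0:
            raise ValueError("season_weeks must be positive")


def n_loss_estimate(n_input_farmer: float, season_weeks: float) -> float:
    """Expected seasonal N loss under farmer-practice input, kg N ha-1."""
    if n_input_farmer < 0 or season_weeks < 0:
        raise ValueError("inputs must be non-negative")
    return n_input_farmer * LOSS_RATE_PER_WEEK * season_weeks


def recommend_n(inputs: RecommendationInputs) -> float:
    """Optimal fertiliser dose N_opt (kg N ha-1), clamped at zero."""
    loss = n_loss_estimate(inputs.n_input_farmer, inputs.season_weeks)
    n_opt = (
        inputs.n_upt + inputs.n_res + loss
        - inputs.n_ini - inputs.n_hum - inputs.n_root
    )
    return max(0.0, n_opt)


def reduced_rate(n_opt: float, fraction: float = 0.8) -> float:
    """Reduced-dose variant (e.g. 80 % of the recommendation)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if n_opt < 0:
        raise ValueError("n_opt must be non-negative")
    return n_opt * fraction
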