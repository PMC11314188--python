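"""Model-evaluation statistics: RMSE, Nash-Sutcliffe E, Willmott d.

For simulated values P and observations O:

    RMSE = sqrt( sum (P_i - O_i)^2 / n )
    E    = 1 - sum (O_i - P_i)^2 / sum (O_i - Obar)^2
    d    = 1 - sum (O_i - P_i)^2 / sum (|P_i - Obar| + |O_i - Obar|)^2

E ranges over (-inf, 1] with 1 a perfect fit and 0 no better than the
observed mean; d is bounded in [0, 1]. Following the common hydrological
convention, a simulation is judged acceptable when E > 0.36 and d > 0.7
(both strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalStats", "rmse", "nse", "agreement_d", "evaluate_series",
           "acceptance_check", "E_THRESHOLD", "D_THRESHOLD"]

E_THRESHOLD = 0.36
D_THRESHOLD = 0.7


@dataclass(frozen=True)
class EvalStats:
    """RMSE / E / d triple for one prediction-observation pairing."""

    rmse: float
    nse: float
    agreement: float
    n: int


def _pair(p, o) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    o = np.asarray(o, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError(f"series shapes differ: {p.shape} vs {o.shape}")
    if p.size < 1:
        raise ValueError("need at least one sample")
    return p, o


def rmse(p, o) -> float:
    """Root mean square error, in the units of the variable."""
    p, o = _pair(p, o)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def nse(p, o) -> float:
    """Nash-Sutcliffe model efficiency E."""
    p, o = _pair(p, o)
    if p.size < 2:
        raise ValueError("E needs at least two samples")
    denom = float(np.sum((o - o.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("E undefined for constant observations")
    return 1.0 - float(np.sum((o - p) ** 2)) / denom


def agreement_d(p, o) -> float:
    """Willmott index of agreement d."""
    p, o = _pair(p, o)
    if p.size < 2:
        raise ValueError("d needs at least two samples")
    obar = o.mean()
    denom = float(np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2))
    if denom == 0.0:
        raise ValueError("d undefined: no deviation from the observed mean")
    return 1.0 - float(np.sum((o - p) ** 2)) / denom


def evaluate_series(p, o) -> EvalStats:
    """All three statistics for one pairing."""
    p, o = _pair(p, o)
    return EvalStats(rmse=rmse(p, o), nse=nse(p, o),
                     agreement=agreement_d(p, o), n=int(p.size))


def acceptance_check(stats: EvalStats) -> dict[str, bool]:
    """Strict-threshold verdict: E > 0.36 and d > 0.7.

    Returns per-criterion booleans plus the combined ``acceptable``.
    """
    e_ok = stats.nse > E_THRESHOLD
    d_ok = stats.agreement > D_THRESHOLD
    return {"e_ok": e_ok, "d_ok": d_ok, "acceptable": e_ok and d_ok}
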