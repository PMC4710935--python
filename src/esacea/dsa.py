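"""Deterministic sensitivity analysis: one-way and two-way multiplicative
variation of the four base-case inputs (per-arm annual cost and
effectiveness), with tornado-style summaries.

Each scenario recomputes the full incremental analysis and flags whether the
willingness-to-pay decision flips relative to the base case. Effectiveness
is clamped to [0, 1] after multiplication (with a warning when clamping
occurs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import CEAConfig, CEAResult, Dominance
from .engine import icer

PARAMETERS = ("cost_epob", "cost_cera", "eff_epob", "eff_cera")
DEFAULT_MULTIPLIERS = (0.9, 1.1)  # the reported +/-10% variation


@dataclass(frozen=True)
class CEAInputs:
    """The four scalars the sensitivity analyses perturb."""

    cost_epob: float
    eff_epob: float
    cost_cera: float
    eff_cera: float

    def varied(self, parameter: str, multiplier: float) -> "CEAInputs":
        if parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")
        value = getattr(self, parameter) * multiplier
        if parameter.startswith("eff_") and not 0.0 <= value <= 1.0:
            warnings.warn(
                f"{parameter} x {multiplier} = {value:.4f} clamped to [0, 1]",
                stacklevel=2,
            )
            value = min(max(value, 0.0), 1.0)
        return replace(self, **{parameter: value})

    def evaluate(self, config: CEAConfig) -> CEAResult:
        return icer(self.cost_epob, self.eff_epob, self.cost_cera, self.eff_cera, config=config)


@dataclass
class DSAScenario:
    parameter: str
    low_multiplier: float
    high_multiplier: float
    result_low: CEAResult
    result_high: CEAResult
    base: CEAResult
    decision_changed: bool


def one_way(
    base: CEAInputs,
    parameter: str,
    config: CEAConfig,
    multipliers: Tuple[float, float] = DEFAULT_MULTIPLIERS,
) -> DSAScenario:
    """Recompute the CEA at the low and high bound of one parameter."""
    lo, hi = multipliers
    if not lo < hi:
        raise ValueError("low multiplier must be < high multiplier")
    base_result = base.evaluate(config)
    result_low = base.varied(parameter, lo).evaluate(config)
    result_high = base.varied(parameter, hi).evaluate(config)
    changed = (
        result_low.cost_effective_at_threshold != base_result.cost_effective_at_threshold
        or result_high.cost_effective_at_threshold != base_result.cost_effective_at_threshold
    )
    return DSAScenario(parameter, lo, hi, result_low, result_high, base_result, changed)


def two_way(
    base: CEAInputs,
    parameter_pair: Tuple[str, str],
    config: CEAConfig,
    grid: Sequence[float] = (0.9, 1.0, 1.1),
    grid2: Sequence[float] = None,
) -> List[List[CEAResult]]:
    """Full-factorial recomputation over a multiplier grid for two parameters.

    Returns a matrix indexed [i][j] for the i-th multiplier of the first
    parameter and j-th of the second; the (1.0, 1.0) cell equals the base
    case.
    """
    p1, p2 = parameter_pair
    if p1 == p2:
        raise ValueError("two-way analysis needs two distinct parameters")
    grid2 = grid if grid2 is None else grid2
    return [
        [base.varied(p1, m1).varied(p2, m2).evaluate(config) for m2 in grid2]
        for m1 in grid
    ]


def icer_matrix(results: List[List[CEAResult]]) -> np.ndarray:
    return np.array([[r.icer for r in row] for row in results])


def tornado(
    base: CEAInputs,
    config: CEAConfig,
    multipliers: Tuple[float, float] = DEFAULT_MULTIPLIERS,
    parameters: Sequence[str] = PARAMETERS,
) -> pd.DataFrame:
    """One-way scenarios for every parameter as a tidy tornado table."""
    rows = []
    for p in parameters:
        sc = one_way(base, p, config, multipliers)
        for bound, res in (("low", sc.result_low), ("high", sc.result_high)):
            rows.append(
                {
                    "parameter": p,
                    "bound": bound,
                    "multiplier": sc.low_multiplier if bound == "low" else sc.high_multiplier,
                    "delta_cost": res.delta_cost,
                    "delta_eff": res.delta_eff,
                    "icer": res.icer,
                    "dominance": res.dominance.value,
                    "cost_effective": res.cost_effective_at_threshold,
                    "decision_changed": res.cost_effective_at_threshold
                    != sc.base.cost_effective_at_threshold,
                }
            )
    return pd.DataFrame(rows)
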