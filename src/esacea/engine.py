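"""Two-arm decision tree, rollback, ACER/ICER, dominance and threshold call.

Each arm is a chance node with two leaves: success (phase-mean Hb in the
target range, effectiveness payoff 1, leaf cost = mean cost among in-range
patients) and failure (payoff 0, leaf cost = mean cost among out-of-range
patients). Rolling back gives E[cost] = p*c_s + (1-p)*c_f and E[eff] = p.

The incremental cost-effectiveness ratio (ICER) of CERA versus EpoB is
(C_CERA - C_EpoB) / (E_CERA - E_EpoB), reported with its sign together with
the cost-effectiveness-plane quadrant, since a negative ratio alone does not
distinguish dominance from being dominated. The willingness-to-pay threshold
is 3x per-capita GDP; the decision is taken on net monetary benefit,
NMB = lambda*dE - dC >= 0, which reduces to ICER <= lambda in the NE quadrant
and ICER >= lambda in the SW quadrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .datamodel import (
    Arm,
    ArmSummary,
    CEAConfig,
    CEAResult,
    Dominance,
    EffectivenessMode,
)
from .costing import annualize


@dataclass(frozen=True)
class ArmNode:
    """Chance node for one arm: success probability and the two leaf costs."""

    p_success: float
    cost_success: float
    cost_fail: float

    def __post_init__(self):
        if not 0.0 <= self.p_success <= 1.0:
            raise ValueError(f"success probability {self.p_success} outside [0, 1]")
        if self.cost_success < 0 or self.cost_fail < 0:
            raise ValueError("leaf costs must be non-negative")


@dataclass(frozen=True)
class DecisionTree:
    epob: ArmNode
    cera: ArmNode


def rollback(node: ArmNode) -> Tuple[float, float]:
    """Expected (cost, effectiveness) of a chance node.

    The success leaf pays effectiveness 1, the failure leaf 0, so expected
    effectiveness equals the success probability.
    """
    p = node.p_success
    expected_cost = p * node.cost_success + (1.0 - p) * node.cost_fail
    return expected_cost, p


def rollback_tree(tree: DecisionTree) -> dict:
    """Roll back both arms; returns {Arm: (expected cost, expected effectiveness)}."""
    return {Arm.EPOB: rollback(tree.epob), Arm.CERA: rollback(tree.cera)}


def acer(cost: float, effectiveness: float) -> float:
    """Average cost-effectiveness ratio: mean cost / mean effectiveness.

    Returns NaN (undefined) rather than raising when effectiveness is zero.
    """
    if effectiveness == 0:
        return math.nan
    return cost / effectiveness


def _dominance(delta_cost: float, delta_eff: float) -> Dominance:
    # Strict quadrants; axis points fall to the adjoining trade-off label so
    # DOMINANT/DOMINATED always imply strict inequalities.
    if delta_cost < 0 and delta_eff > 0:
        return Dominance.DOMINANT
    if delta_cost > 0 and delta_eff < 0:
        return Dominance.DOMINATED
    if delta_cost >= 0 and delta_eff >= 0:
        return Dominance.TRADEOFF_NE
    return Dominance.TRADEOFF_SW


def icer(
    cost_epob: float,
    eff_epob: float,
    cost_cera: float,
    eff_cera: float,
    config: Optional[CEAConfig] = None,
) -> CEAResult:
    """Incremental analysis of CERA versus EpoB.

    When a config is given the net-monetary-benefit threshold decision is
    filled in; otherwise it is left None.
    """
    for v in (cost_epob, eff_epob, cost_cera, eff_cera):
        if not math.isfinite(v):
            raise ValueError("CEA inputs must be finite")
    delta_cost = cost_cera - cost_epob
    delta_eff = eff_cera - eff_epob
    defined = delta_eff != 0
    ratio = delta_cost / delta_eff if defined else math.nan
    result = CEAResult(
        cost_epob=cost_epob,
        cost_cera=cost_cera,
        eff_epob=eff_epob,
        eff_cera=eff_cera,
        acer_epob=acer(cost_epob, eff_epob),
        acer_cera=acer(cost_cera, eff_cera),
        delta_cost=delta_cost,
        delta_eff=delta_eff,
        icer=ratio,
        icer_defined=defined,
        dominance=_dominance(delta_cost, delta_eff),
    )
    if config is not None:
        result.cost_effective_at_threshold = threshold_decision(result, config)
    return result


def threshold_decision(result: CEAResult, config: CEAConfig) -> bool:
    """Cost-effective at the willingness-to-pay threshold?

    Net monetary benefit lambda*dE - dC >= 0 at lambda = 3x per-capita GDP
    (or the configured override). Dominant results are always cost-effective,
    dominated ones never; in the NE quadrant this is ICER <= lambda and in
    the SW quadrant ICER >= lambda (savings outweigh the effectiveness lost).
    """
    lam = config.wtp_threshold
    nmb = lam * result.delta_eff - result.delta_cost
    return nmb >= 0


def tree_from_summaries(epob: ArmSummary, cera: ArmSummary) -> DecisionTree:
    """Build the decision tree from per-arm summaries.

    Leaf costs are annualized per-range mean costs; when a per-range cost is
    unavailable (not published, or an empty group) both leaves fall back to
    the arm-mean annual cost, so rollback returns the arm mean exactly.
    """

    def node(s: ArmSummary) -> ArmNode:
        if s.cost_success is None or s.cost_fail is None:
            return ArmNode(s.csr, s.mean_cost_1yr, s.mean_cost_1yr)
        return ArmNode(s.csr, annualize(s.cost_success), annualize(s.cost_fail))

    return DecisionTree(epob=node(epob), cera=node(cera))


def run_cea(epob: ArmSummary, cera: ArmSummary, config: CEAConfig) -> CEAResult:
    """Full base-case analysis from per-arm summaries.

    Expected costs come from rolling back the decision tree. Effectiveness
    follows ``config.effectiveness_mode``: the arm summaries'
    ``avg_effectiveness`` (TABLE replay) or the computed CSR.
    """
    expectations = rollback_tree(tree_from_summaries(epob, cera))
    cost_e, csr_e = expectations[Arm.EPOB]
    cost_c, csr_c = expectations[Arm.CERA]
    if config.effectiveness_mode is EffectivenessMode.TABLE:
        eff_e, eff_c = epob.avg_effectiveness, cera.avg_effectiveness
    else:
        eff_e, eff_c = csr_e, csr_c
    return icer(cost_e, eff_e, cost_c, eff_c, config=config)
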