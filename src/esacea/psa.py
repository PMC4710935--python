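"""Probabilistic sensitivity analysis by Monte Carlo simulation.

Parameter uncertainty is propagated by sampling the four base-case inputs
(per-arm annual cost and effectiveness) from configured distributions —
log-normal for costs, normal for effectiveness (risks), per the model's
convention — and re-running the incremental analysis for every draw. Outputs
are the cost-effectiveness plane (delta-effectiveness vs delta-cost),
quadrant shares, the per-draw ICER distribution, and the cost-effectiveness
acceptability curve (CEAC): the probability of positive net monetary benefit
as a function of the willingness-to-pay threshold.

The published model does not print its PSA distribution parameters; the
default specification is a reconstruction — costs LogNormal(arm mean annual
cost, SD = annual SD / sqrt(n), the standard error of the mean) and
effectiveness Normal(CSR, binomial standard error) — with every value
overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import ArmSummary, CEAConfig, Dominance
from .dsa import CEAInputs
from .engine import icer


class DistFamily(str, Enum):
    NORMAL = "NORMAL"
    LOGNORMAL = "LOGNORMAL"
    BETA = "BETA"
    FIXED = "FIXED"


@dataclass(frozen=True)
class ParamDist:
    """One sampled parameter: family plus arithmetic-scale location/scale.

    LOGNORMAL is parameterized by its arithmetic mean and SD, converted
    internally to log-scale (sigma^2 = ln(1 + sd^2/m^2), mu = ln m -
    sigma^2/2); the mean must then be positive. BETA is parameterized by
    mean and SD via the method of moments.
    """

    family: DistFamily
    location: float
    scale: float = 0.0

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.family is DistFamily.LOGNORMAL and self.scale > 0 and self.location <= 0:
            raise ValueError("lognormal mean parameterization requires a positive mean")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family is DistFamily.FIXED or self.scale == 0:
            return np.full(size, self.location)
        if self.family is DistFamily.NORMAL:
            return rng.normal(self.location, self.scale, size)
        if self.family is DistFamily.LOGNORMAL:
            m, s = self.location, self.scale
            sigma2 = math.log(1.0 + (s / m) ** 2)
            mu = math.log(m) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), size)
        if self.family is DistFamily.BETA:
            m, s = self.location, self.scale
            if not 0 < m < 1:
                raise ValueError("beta mean must be in (0, 1)")
            nu = m * (1 - m) / s ** 2 - 1.0
            if nu <= 0:
                raise ValueError("beta SD too large for the given mean")
            return rng.beta(m * nu, (1 - m) * nu, size)
        raise ValueError(f"unsupported family {self.family}")


class Correlation(str, Enum):
    INDEPENDENT = "INDEPENDENT"
    PAIRED_BOOTSTRAP = "PAIRED_BOOTSTRAP"  # declared; sampling not implemented


@dataclass
class PSASpec:
    """Sampling specification for the four inputs."""

    cost_epob: ParamDist
    cost_cera: ParamDist
    eff_epob: ParamDist
    eff_cera: ParamDist
    n_iterations: int = 50_000
    seed: int = 0
    correlation: Correlation = Correlation.INDEPENDENT

    def __post_init__(self):
        self.correlation = Correlation(self.correlation)
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def default_spec(
    epob: ArmSummary,
    cera: ArmSummary,
    config: CEAConfig,
    n_iterations: Optional[int] = None,
    seed: Optional[int] = None,
) -> PSASpec:
    """Reconstructed default distributions from per-arm summaries.

    Costs: LogNormal(mean annual cost, annual SD / sqrt(n)). Effectiveness:
    Normal(CSR, sqrt(CSR(1-CSR)/n)); draws are truncated to [0, 1] at
    sampling time.
    """

    def cost_dist(s: ArmSummary) -> ParamDist:
        return ParamDist(
            DistFamily.LOGNORMAL,
            s.mean_cost_1yr,
            2.0 * s.sd_cost_6mo / math.sqrt(s.n),
        )

    def eff_dist(s: ArmSummary) -> ParamDist:
        se = math.sqrt(s.csr * (1.0 - s.csr) / s.n)
        return ParamDist(DistFamily.NORMAL, s.csr, se)

    return PSASpec(
        cost_epob=cost_dist(epob),
        cost_cera=cost_dist(cera),
        eff_epob=eff_dist(epob),
        eff_cera=eff_dist(cera),
        n_iterations=n_iterations if n_iterations is not None else config.psa_iterations,
        seed=seed if seed is not None else config.rng_seed,
    )


QUADRANTS = ("NE", "SE", "SW", "NW")  # (dE>0,dC>0), (dE>0,dC<0), (dE<0,dC<0), (dE<0,dC>0)


def quadrant_of(delta_cost: float, delta_eff: float) -> str:
    """Cost-effectiveness-plane quadrant; SE (more effective, cheaper) is
    dominance of the new arm.

    Boundary points (delta_cost = 0 or delta_eff = 0) are assigned to the
    adjacent quadrant clockwise (viewing effectiveness on x and cost on y),
    deterministically.
    """
    x, y = delta_eff, delta_cost
    if x > 0 and y > 0:
        return "NE"
    if x > 0 and y < 0:
        return "SE"
    if x < 0 and y < 0:
        return "SW"
    if x < 0 and y > 0:
        return "NW"
    # axes: rotate the point infinitesimally clockwise
    if x > 0:   # +x axis -> SE
        return "SE"
    if x < 0:   # -x axis -> NW
        return "NW"
    if y > 0:   # +y axis -> NE
        return "NE"
    if y < 0:   # -y axis -> SW
        return "SW"
    return "NE"  # origin, by convention


@dataclass
class PSAResult:
    """Monte Carlo draws and their summaries."""

    delta_cost: np.ndarray
    delta_eff: np.ndarray
    icers: np.ndarray          # NaN where delta_eff == 0
    quadrant_shares: Dict[str, float]
    icer_quantiles: Tuple[float, float, float]  # 2.5%, 50%, 97.5%
    undefined_share: float     # draws with delta_eff == 0, excluded from ICERs

    @property
    def n_draws(self) -> int:
        return self.delta_cost.size

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost, "delta_eff": self.delta_eff})


def sample_draws(spec: PSASpec, config: CEAConfig) -> PSAResult:
    """Run the Monte Carlo PSA: sample the inputs, re-run the incremental
    analysis per draw through the decision engine, and summarize.

    Deterministic for a fixed ``spec.seed``. Effectiveness draws are
    truncated to [0, 1].
    """
    if spec.correlation is not Correlation.INDEPENDENT:
        raise NotImplementedError(
            "only independent parameter sampling is implemented; paired-bootstrap "
            "correlation requires patient-level resampling"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_iterations
    cost_e = spec.cost_epob.sample(rng, n)
    cost_c = spec.cost_cera.sample(rng, n)
    eff_e = np.clip(spec.eff_epob.sample(rng, n), 0.0, 1.0)
    eff_c = np.clip(spec.eff_cera.sample(rng, n), 0.0, 1.0)

    dc = np.empty(n)
    de = np.empty(n)
    ic = np.empty(n)
    for i in range(n):  # each draw goes through the engine, not a re-derivation
        res = icer(cost_e[i], eff_e[i], cost_c[i], eff_c[i])
        dc[i] = res.delta_cost
        de[i] = res.delta_eff
        ic[i] = res.icer

    counts = {q: 0 for q in QUADRANTS}
    for i in range(n):
        counts[quadrant_of(dc[i], de[i])] += 1
    shares = {q: counts[q] / n for q in QUADRANTS}

    defined = ~np.isnan(ic)
    undefined_share = float(1.0 - defined.sum() / n)
    if defined.any():
        q = np.quantile(ic[defined], [0.025, 0.5, 0.975])
        quantiles = (float(q[0]), float(q[1]), float(q[2]))
    else:
        quantiles = (math.nan, math.nan, math.nan)

    return PSAResult(dc, de, ic, shares, quantiles, undefined_share)


def ceac(result: PSAResult, lambdas: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value the probability that the net monetary
    benefit lambda*dE - dC is strictly positive.
    """
    if result.n_draws == 0:
        raise ValueError("no draws")
    lambdas = np.asarray(list(lambdas), dtype=float)
    probs = [
        float(np.mean(lam * result.delta_eff - result.delta_cost > 0.0))
        for lam in lambdas
    ]
    return pd.DataFrame({"lambda": lambdas, "probability": probs})


def icer_distribution(result: PSAResult, base_icer: float) -> dict:
    """Quantile summary of per-draw ICERs and the share within 10% of base.

    Zero-delta-effectiveness draws are excluded (reported as
    ``undefined_share``). The +/-10% band bounds are ordered numerically so
    a negative base ICER yields [base*1.1, base*0.9].
    """
    lo, hi = sorted((base_icer * 0.9, base_icer * 1.1))
    defined = result.icers[~np.isnan(result.icers)]
    share = float(np.mean((defined >= lo) & (defined <= hi))) if defined.size else math.nan
    return {
        "q2.5": result.icer_quantiles[0],
        "median": result.icer_quantiles[1],
        "q97.5": result.icer_quantiles[2],
        "share_within_10pct": share,
        "undefined_share": result.undefined_share,
    }
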