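"""Drug-acquisition costing: currency conversion, inflation, annualization,
discounting.

The payer perspective covers drug-acquisition costs only; hospitalization,
visits and monitoring are assumed equal across arms and excluded. Costs
collected in Moroccan dirhams are converted at the configured MAD/USD rate
and inflated by a single multiplicative index factor. A 6-month phase cost is
annualized by doubling (two identical half-year blocks); the base-case
horizon is one year with all costs in year 0, so the 3% discount rate only
bites in multi-year extensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .datamodel import Arm, CEAConfig, PatientPhaseRecord


class CurrencySource(str, Enum):
    USD = "USD"
    MAD = "MAD"


@dataclass(frozen=True)
class CostBreakdown:
    patient_id: str
    arm: Arm
    cost_6mo: float
    cost_1yr: float
    currency_source: CurrencySource = CurrencySource.USD


def convert_currency(amount_mad: float, rate_mad_per_usd: float) -> float:
    """Convert dirhams to dollars at ``rate_mad_per_usd`` dirhams per dollar."""
    if rate_mad_per_usd <= 0:
        raise ValueError("exchange rate must be positive")
    return amount_mad / rate_mad_per_usd


def annualize(cost_6mo: float) -> float:
    """Project a 6-month phase cost to one year by doubling."""
    if cost_6mo < 0:
        raise ValueError("cost must be non-negative")
    return 2.0 * cost_6mo


def discount(cost: float, rate: float, year_index: int) -> float:
    """Present value of ``cost`` incurred in ``year_index`` (year 0 undiscounted)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if year_index < 0:
        raise ValueError("year index must be >= 0")
    return cost / (1.0 + rate) ** year_index


def patient_costs(
    records: Sequence[PatientPhaseRecord],
    config: CEAConfig,
    currency_source: CurrencySource = CurrencySource.USD,
) -> list:
    """Per-patient 6-month and annual costs in USD.

    MAD-denominated inputs are converted at ``config.exchange_mad_per_usd``;
    all costs are scaled by ``config.inflation_factor`` and discounted at the
    configured rate (year 0 in the base case, hence unchanged).
    """
    out = []
    for r in records:
        c6 = sum(r.cost_monthly) * config.inflation_factor
        if currency_source is CurrencySource.MAD:
            c6 = convert_currency(c6, config.exchange_mad_per_usd)
        c1 = discount(annualize(c6), config.discount_rate, 0)
        out.append(CostBreakdown(r.patient_id, r.arm, c6, c1, currency_source))
    return out


def cost_table(breakdowns: Sequence[CostBreakdown]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [b.patient_id for b in breakdowns],
            "arm": [b.arm.value for b in breakdowns],
            "cost_6mo": [b.cost_6mo for b in breakdowns],
            "cost_1yr": [b.cost_1yr for b in breakdowns],
        }
    )
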