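"""Hb-range classification and per-arm effectiveness summaries.

Each patient-phase is classified by the mean of its six monthly haemoglobin
values against the target range (default 10.5-12 g/dL, closed interval).
Clinical success rate (CSR) is the in-range proportion; out-of-range patients
(below and above pooled) count as treatment failures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .datamodel import (
    Arm,
    ArmSummary,
    CEAConfig,
    EffectivenessMode,
    PatientPhaseRecord,
)
from .costing import annualize, discount


class HbCategory(str, Enum):
    IN_RANGE = "IN_RANGE"
    BELOW = "BELOW"
    ABOVE = "ABOVE"


@dataclass(frozen=True)
class PhaseClassification:
    patient_id: str
    arm: Arm
    mean_hb: float
    category: HbCategory


def classify_phase(record: PatientPhaseRecord, config: CEAConfig) -> PhaseClassification:
    """Classify one patient-phase by its mean Hb against the target range.

    With ``config.closed_interval`` (default) both endpoints count as in
    range; the half-open variant excludes them.
    """
    mean = record.mean_hb
    if config.closed_interval:
        in_range = config.hb_low <= mean <= config.hb_high
    else:
        in_range = config.hb_low < mean < config.hb_high
    if in_range:
        cat = HbCategory.IN_RANGE
    elif mean < config.hb_low:
        cat = HbCategory.BELOW
    else:
        cat = HbCategory.ABOVE
    return PhaseClassification(record.patient_id, record.arm, mean, cat)


def summarize_arm(
    records: Sequence[PatientPhaseRecord],
    config: CEAConfig,
    classifications: Optional[Sequence[PhaseClassification]] = None,
    table_effectiveness: Optional[float] = None,
) -> ArmSummary:
    """Aggregate one arm's records into counts, CSR, and per-range costs.

    ``cost_success``/``cost_fail`` are mean 6-month drug costs within the
    in-range and out-of-range groups; a group with no patients yields None
    (undefined). ``avg_effectiveness`` follows ``config.effectiveness_mode``:
    the CSR, or a caller-supplied table value when replaying published inputs.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty arm")
    arms = {r.arm for r in records}
    if len(arms) != 1:
        raise ValueError(f"records span multiple arms: {sorted(a.value for a in arms)}")
    arm = arms.pop()
    if classifications is None:
        classifications = [classify_phase(r, config) for r in records]

    n = len(records)
    success = [r for r, c in zip(records, classifications) if c.category is HbCategory.IN_RANGE]
    fail = [r for r, c in zip(records, classifications) if c.category is not HbCategory.IN_RANGE]
    csr = len(success) / n

    if config.effectiveness_mode is EffectivenessMode.TABLE:
        if table_effectiveness is None:
            raise ValueError("effectiveness_mode TABLE requires table_effectiveness")
        avg_eff = table_effectiveness
    else:
        avg_eff = csr

    costs = pd.Series([r.cost_6mo for r in records], dtype=float)
    mean_6mo = float(costs.mean())
    # discounting is a no-op at the default 1-year horizon (costs in year 0)
    mean_1yr = discount(annualize(mean_6mo), config.discount_rate, 0)
    return ArmSummary(
        arm=arm,
        n=n,
        n_success=len(success),
        n_fail=len(fail),
        csr=csr,
        avg_effectiveness=avg_eff,
        mean_cost_6mo=mean_6mo,
        sd_cost_6mo=float(costs.std(ddof=1)) if n > 1 else 0.0,
        mean_cost_1yr=mean_1yr,
        cost_success=sum(r.cost_6mo for r in success) / len(success) if success else None,
        cost_fail=sum(r.cost_6mo for r in fail) / len(fail) if fail else None,
    )


def range_proportions(classifications: Sequence[PhaseClassification]) -> tuple:
    """Proportions (below, in range, above); they sum to 1."""
    if not classifications:
        raise ValueError("no classifications supplied")
    n = len(classifications)
    below = sum(c.category is HbCategory.BELOW for c in classifications) / n
    within = sum(c.category is HbCategory.IN_RANGE for c in classifications) / n
    above = sum(c.category is HbCategory.ABOVE for c in classifications) / n
    return below, within, above


def cohort_summaries(
    records: Sequence[PatientPhaseRecord], config: CEAConfig
) -> "dict[Arm, ArmSummary]":
    """Summarize a full cohort into one ArmSummary per arm.

    Patient-level runs have no external effectiveness table, so the CSR is
    used for ``avg_effectiveness`` regardless of ``config.effectiveness_mode``.
    """
    csr_config = (
        config
        if config.effectiveness_mode is EffectivenessMode.CSR
        else replace(config, effectiveness_mode=EffectivenessMode.CSR)
    )
    out = {}
    for arm in Arm:
        arm_records = [r for r in records if r.arm is arm]
        if arm_records:
            out[arm] = summarize_arm(arm_records, csr_config)
    return out


def classification_table(classifications: Sequence[PhaseClassification]) -> pd.DataFrame:
    """Tidy per-patient classification table (patient_id, arm, mean_hb, category)."""
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in classifications],
            "arm": [c.arm.value for c in classifications],
            "mean_hb": [c.mean_hb for c in classifications],
            "category": [c.category.value for c in classifications],
        }
    )
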