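"""Domain types and delimited-text I/O for the two-arm ESA cost-effectiveness model.

The analysis compares once-monthly CERA (continuous erythropoiesis receptor
activator) against thrice-weekly epoetin beta (EpoB) in chronic haemodialysis
patients. Effectiveness is the clinical success rate (CSR): the proportion of
patients whose phase-mean haemoglobin lies in the 10.5-12 g/dL target range.
Costs are annual drug-acquisition costs from the health-care payer perspective.

Patient-level data are stored wide: one row per patient-phase with exactly six
monthly Hb, dose and cost columns, because the study protocol classifies each
phase by the mean of six consecutive monthly measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

N_MONTHS = 6  # monthly measures per treatment phase

HB_COLS = [f"hb_{i}" for i in range(1, N_MONTHS + 1)]
DOSE_COLS = [f"dose_{i}" for i in range(1, N_MONTHS + 1)]
COST_COLS = [f"cost_{i}" for i in range(1, N_MONTHS + 1)]
REQUIRED_COLS = ["patient_id", "arm"] + HB_COLS + DOSE_COLS + COST_COLS


class Arm(str, Enum):
    """Treatment arm: epoetin beta (thrice weekly) or CERA (once monthly)."""

    EPOB = "EPOB"
    CERA = "CERA"


class Dominance(str, Enum):
    """Quadrant of the cost-effectiveness plane for the incremental result.

    DOMINANT: new arm cheaper and more effective (south-east quadrant).
    DOMINATED: new arm costlier and less effective (north-west).
    TRADEOFF_NE: costlier but more effective; TRADEOFF_SW: cheaper but less
    effective.
    """

    DOMINANT = "DOMINANT"
    DOMINATED = "DOMINATED"
    TRADEOFF_NE = "TRADEOFF_NE"
    TRADEOFF_SW = "TRADEOFF_SW"


class EffectivenessMode(str, Enum):
    """Which per-arm effectiveness feeds the engine.

    CSR uses the computed success proportion. TABLE replays an externally
    supplied average effectiveness (the published model's 0.55/0.59, whose
    derivation from CSR is not stated); the two are never interchanged
    silently.
    """

    CSR = "CSR"
    TABLE = "TABLE"


@dataclass(frozen=True)
class PatientPhaseRecord:
    """One patient in one treatment phase: six monthly Hb/dose/cost values.

    Doses are IU/week for EPOB and ug/month for CERA; costs are in the
    configured currency (USD by default).
    """

    patient_id: str
    arm: Arm
    hb_monthly: tuple
    dose_monthly: tuple
    cost_monthly: tuple
    ferritin: Optional[float] = None
    tsat: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "hb_monthly", tuple(float(x) for x in self.hb_monthly))
        object.__setattr__(self, "dose_monthly", tuple(float(x) for x in self.dose_monthly))
        object.__setattr__(self, "cost_monthly", tuple(float(x) for x in self.cost_monthly))
        if len(self.hb_monthly) != N_MONTHS:
            raise ValueError(
                f"patient {self.patient_id}: expected {N_MONTHS} monthly Hb values, "
                f"got {len(self.hb_monthly)}"
            )
        if len(self.dose_monthly) != N_MONTHS or len(self.cost_monthly) != N_MONTHS:
            raise ValueError(
                f"patient {self.patient_id}: doses and costs must each have {N_MONTHS} entries"
            )
        for m, hb in enumerate(self.hb_monthly, start=1):
            if not math.isfinite(hb):
                raise ValueError(f"patient {self.patient_id}, month {m}: missing or non-finite Hb")
            if not 3.0 < hb < 20.0:
                raise ValueError(
                    f"patient {self.patient_id}, month {m}: Hb {hb} g/dL outside plausible (3, 20)"
                )
        if any(d < 0 for d in self.dose_monthly):
            raise ValueError(f"patient {self.patient_id}: negative dose")
        if any(c < 0 for c in self.cost_monthly):
            raise ValueError(f"patient {self.patient_id}: negative cost")

    @property
    def mean_hb(self) -> float:
        return sum(self.hb_monthly) / N_MONTHS

    @property
    def cost_6mo(self) -> float:
        return sum(self.cost_monthly)


@dataclass
class ArmSummary:
    """Per-arm aggregates feeding the decision tree.

    ``csr`` is the success proportion; ``avg_effectiveness`` may differ from it
    when replaying published model inputs. ``cost_success``/``cost_fail`` are
    mean 6-month costs within the in-range / out-of-range groups (None when a
    group is empty).
    """

    arm: Arm
    n: int
    n_success: int
    n_fail: int
    csr: float
    avg_effectiveness: float
    mean_cost_6mo: float
    sd_cost_6mo: float
    mean_cost_1yr: float
    cost_success: Optional[float] = None
    cost_fail: Optional[float] = None

    def __post_init__(self):
        if self.n_success + self.n_fail != self.n:
            raise ValueError("n_success + n_fail must equal n")
        if not math.isclose(self.csr, self.n_success / self.n, abs_tol=1e-9):
            raise ValueError("csr must equal n_success / n")


@dataclass
class CEAConfig:
    """Run configuration: Hb target range, economics, and PSA settings.

    Defaults reproduce the base case: target range 10.5-12 g/dL (closed
    interval), 1-year horizon, 3% discount rate (a no-op at one year, costs
    incurred in year 0), exchange rate 9.297 MAD/USD, willingness-to-pay
    threshold 3x the 2013 Moroccan per-capita GDP of 3092 $.
    """

    hb_low: float = 10.5
    hb_high: float = 12.0
    closed_interval: bool = True
    discount_rate: float = 0.03
    horizon_years: int = 1
    exchange_mad_per_usd: float = 9.297
    inflation_factor: float = 1.0
    gdp_per_capita_usd: float = 3092.0
    threshold_multiplier: float = 3.0
    threshold_usd: Optional[float] = None  # literal override of 3xGDP
    psa_iterations: int = 50_000
    rng_seed: int = 0
    effectiveness_mode: EffectivenessMode = EffectivenessMode.TABLE

    def __post_init__(self):
        self.effectiveness_mode = EffectivenessMode(self.effectiveness_mode)
        if not self.hb_low < self.hb_high:
            raise ValueError("hb_low must be < hb_high")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.psa_iterations < 1:
            raise ValueError("psa_iterations must be >= 1")
        if self.exchange_mad_per_usd <= 0:
            raise ValueError("exchange rate must be positive")

    @property
    def wtp_threshold(self) -> float:
        """Willingness-to-pay threshold in $ per unit effectiveness."""
        if self.threshold_usd is not None:
            return self.threshold_usd
        return self.threshold_multiplier * self.gdp_per_capita_usd

    @classmethod
    def from_yaml(cls, path) -> "CEAConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["effectiveness_mode"] = self.effectiveness_mode.value
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class CEAResult:
    """Incremental result of CERA vs EpoB with dominance and threshold call.

    ``delta_cost``/``delta_eff`` are CERA minus EpoB. ``icer`` keeps its sign
    (a negative ICER is reported together with the dominance quadrant, since
    the sign alone is ambiguous). ``icer`` is NaN and ``icer_defined`` False
    when ``delta_eff`` is 0.
    """

    cost_epob: float
    cost_cera: float
    eff_epob: float
    eff_cera: float
    acer_epob: float
    acer_cera: float
    delta_cost: float
    delta_eff: float
    icer: float
    icer_defined: bool
    dominance: Dominance
    cost_effective_at_threshold: Optional[bool] = None

    @property
    def icer_per_percentage_point(self) -> float:
        """ICER rescaled to $ per percentage point of CSR (delta_eff / 100)."""
        return self.icer / 100.0 if self.icer_defined else math.nan

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dominance"] = self.dominance.value
        return d


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching hand-rounded report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(proportion: float, ndigits: int = 1) -> str:
    """Render a proportion as a percentage string, one decimal, half-up.

    A trailing ``.0`` is dropped (16.0% prints as ``16``), matching the mixed
    precision of the published tables.
    """
    pct = round_half_up(100.0 * proportion, ndigits)
    if pct == int(pct):
        return str(int(pct))
    return f"{pct:.{ndigits}f}"


# ---------------------------------------------------------------------------
# Cohort file I/O (CSV, one row per patient-arm, wide monthly columns)
# ---------------------------------------------------------------------------

def read_cohort(path, dialect: str = ",") -> list:
    """Read patient-phase records from a delimited text file.

    The header must name ``patient_id``, ``arm`` and the 18 wide monthly
    columns ``hb_1..hb_6``, ``dose_1..dose_6``, ``cost_1..cost_6``; optional
    ``ferritin`` and ``tsat`` columns are carried through.
    """
    df = pd.read_csv(path, sep=dialect, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path}: missing required column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        hb = []
        for col in HB_COLS:
            try:
                hb.append(float(row[col]))
            except (TypeError, ValueError):
                raise ValueError(
                    f"cohort file {path}, row {idx + 2}: non-numeric Hb in column {col!r}: "
                    f"{row[col]!r}"
                ) from None
        records.append(
            PatientPhaseRecord(
                patient_id=str(row["patient_id"]),
                arm=Arm(str(row["arm"]).upper()),
                hb_monthly=tuple(hb),
                dose_monthly=tuple(float(row[c]) for c in DOSE_COLS),
                cost_monthly=tuple(float(row[c]) for c in COST_COLS),
                ferritin=float(row["ferritin"]) if "ferritin" in df.columns and pd.notna(row.get("ferritin")) else None,
                tsat=float(row["tsat"]) if "tsat" in df.columns and pd.notna(row.get("tsat")) else None,
            )
        )
    return records


def cohort_to_frame(records: Sequence[PatientPhaseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "arm": r.arm.value}
        row.update({c: v for c, v in zip(HB_COLS, r.hb_monthly)})
        row.update({c: v for c, v in zip(DOSE_COLS, r.dose_monthly)})
        row.update({c: v for c, v in zip(COST_COLS, r.cost_monthly)})
        row["ferritin"] = r.ferritin
        row["tsat"] = r.tsat
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[PatientPhaseRecord], path, dialect: str = ",") -> None:
    """Write records as CSV with full float precision so read/write round-trips."""
    # 17 significant digits guarantee binary64 round-trip
    cohort_to_frame(records).to_csv(path, sep=dialect, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Published summary inputs (packaged fixture)
# ---------------------------------------------------------------------------

def load_table3_fixture() -> tuple:
    """Per-arm summary inputs of the published base case.

    75 patients per arm; EpoB 49 successes, 6-month cost 1644.2 +/- 859.4 $,
    annual cost 3288.49 $, average effectiveness 0.55; CERA 53 successes,
    1515.5 +/- 713 $, 3030.19 $, 0.59. Per-range leaf costs are not published,
    so ``cost_success``/``cost_fail`` stay None and the decision tree falls
    back to the arm mean at both leaves.
    """
    epob = ArmSummary(
        arm=Arm.EPOB, n=75, n_success=49, n_fail=26, csr=49 / 75,
        avg_effectiveness=0.55, mean_cost_6mo=1644.2, sd_cost_6mo=859.4,
        mean_cost_1yr=3288.49,
    )
    cera = ArmSummary(
        arm=Arm.CERA, n=75, n_success=53, n_fail=22, csr=53 / 75,
        avg_effectiveness=0.59, mean_cost_6mo=1515.5, sd_cost_6mo=713.0,
        mean_cost_1yr=3030.19,
    )
    return epob, cera


# Published Table 2 Hb-range counts (below / in range / above), used by tests
# and the synthetic-cohort calibration targets.
TABLE2_RANGE_COUNTS = {
    Arm.EPOB: (14, 49, 12),
    Arm.CERA: (7, 53, 15),
}
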