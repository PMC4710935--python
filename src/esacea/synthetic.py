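"""Synthetic two-phase haemodialysis cohort under the ESA titration protocol.

No patient-level data are deposited for this study design, so downstream
stages are exercised on a simulated crossover cohort: each of ``n_patients``
contributes an EpoB phase and a CERA phase of six monthly haemoglobin, dose
and drug-cost values.

Model
-----
* Each patient-phase has a latent Hb setpoint drawn from
  Normal(phase mean, setpoint SD); monthly Hb is the setpoint plus a
  stationary AR(1) deviation (marginal SD ``hb_month_sd``, lag-1 correlation
  ``hb_autocorr``). The phase mean over six months is then exactly Normal, so
  the setpoint SD can be calibrated such that P(phase mean in the target
  range) equals a requested clinical success rate — simulated successes are
  Binomial(n, target) by construction.
* Doses start from the observed arm distributions (EpoB 6104 +/- 3178
  IU/week; CERA 106.4 +/- 50.1 ug/month, truncated at a small positive
  floor) and follow the protocol titration each month: -25% when Hb rose by
  more than 1 g/dL over the previous month, +25% when it fell by more than
  1 g/dL, at most one adjustment per month.
* Monthly drug cost = dose x unit price; EpoB weekly doses are costed at
  13/3 weeks per month so a 6-month phase spans 26 weeks.

The conversion table from weekly EpoB to a starting CERA dose
(<8000 IU -> 120 ug, 8000-16000 IU -> 200 ug, >16000 IU -> 360 ug; both
endpoints in the middle tier) is available as ``cera_dose_mode="protocol"``;
the default ``"observed"`` draws steady-state CERA doses directly, which is
what the published phase means reflect after the downward titration the
study observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .datamodel import Arm, N_MONTHS, PatientPhaseRecord

WEEKS_PER_MONTH = 13.0 / 3.0  # 26 weeks per 6-month phase

# Unit prices back-solved so that expected phase costs match the observed
# 6-month means (1644.2 $ over 6104 IU/week x 26 weeks; 1515.5 $ over
# 106.4 ug/month x 6 months).
EPOB_UNIT_PRICE = 1644.2 / (6104 * 26 / 1000)  # $ per 1000 IU
CERA_UNIT_PRICE = 1515.5 / (106.4 * 6)         # $ per ug

TITRATION_STEP = 0.25
TITRATION_TRIGGER = 1.0  # g/dL change per month


@dataclass
class ArmSimParams:
    """Per-arm generator settings (units: g/dL, IU/week or ug/month, $)."""

    baseline_hb_mean: float
    baseline_hb_sd: float
    phase_hb_mean: float
    target_csr: Optional[float]  # None -> use phase_hb_sd directly
    phase_hb_sd: float
    mean_dose: float
    dose_sd: float
    unit_price: float


@dataclass
class SimulationParams:
    """Cohort generator settings; defaults emulate the observed study arms.

    ``dose_response`` (g/dL per dose unit above the arm mean) feeds the dose
    back into the Hb setpoint; it defaults to 0 so the CSR calibration stays
    exact (the titration then tracks Hb without altering it, as in an
    observational phase at steady state).
    """

    n_patients: int = 75
    hb_month_sd: float = 0.4
    hb_autocorr: float = 0.5
    dose_response: float = 0.0
    weeks_per_month: float = WEEKS_PER_MONTH
    cera_dose_mode: str = "observed"  # or "protocol"
    seed: int = 0
    epob: ArmSimParams = field(default_factory=lambda: ArmSimParams(
        baseline_hb_mean=11.14, baseline_hb_sd=1.18,
        phase_hb_mean=11.25, target_csr=49 / 75, phase_hb_sd=0.73,
        mean_dose=6104.0, dose_sd=3178.0, unit_price=EPOB_UNIT_PRICE,
    ))
    cera: ArmSimParams = field(default_factory=lambda: ArmSimParams(
        baseline_hb_mean=11.46, baseline_hb_sd=0.79,
        phase_hb_mean=11.42, target_csr=53 / 75, phase_hb_sd=0.63,
        mean_dose=106.4, dose_sd=50.1, unit_price=CERA_UNIT_PRICE,
    ))
    hb_low: float = 10.5
    hb_high: float = 12.0

    def __post_init__(self):
        if not 0.0 <= self.hb_autocorr < 1.0:
            raise ValueError("hb_autocorr must be in [0, 1)")
        if self.hb_month_sd < 0:
            raise ValueError("hb_month_sd must be >= 0")
        if self.cera_dose_mode not in ("observed", "protocol"):
            raise ValueError("cera_dose_mode must be 'observed' or 'protocol'")
        for arm in (self.epob, self.cera):
            if arm.mean_dose <= 0 or arm.unit_price <= 0:
                raise ValueError("doses and prices must be positive")


@dataclass
class ProtocolState:
    """Titration state carried month to month for one patient."""

    agent: Arm
    current_dose: float
    hb_prev: float
    iron_on: bool = False
    ferritin: float = 300.0
    tsat: float = 30.0


# ---------------------------------------------------------------------------
# Protocol rules
# ---------------------------------------------------------------------------

def convert_epob_to_cera(weekly_epob_iu: float) -> float:
    """Starting monthly CERA dose (ug) from the prior weekly EpoB dose (IU).

    Tiers: below 8000 IU -> 120 ug; 8000 to 16000 IU inclusive -> 200 ug;
    above 16000 IU -> 360 ug. Both tier endpoints belong to the middle tier,
    the only reading consistent with all three clauses of the protocol.
    """
    if weekly_epob_iu <= 0:
        raise ValueError("weekly EpoB dose must be positive")
    if weekly_epob_iu < 8000:
        return 120.0
    if weekly_epob_iu <= 16000:
        return 200.0
    return 360.0


def titrate(state: ProtocolState, hb_now: float) -> float:
    """Dose after one monthly titration step.

    -25% when Hb rose by more than 1 g/dL since last month, +25% when it fell
    by more than 1 g/dL, otherwise unchanged; never more than one adjustment.
    """
    if state.current_dose <= 0:
        raise ValueError("current dose must be positive while on therapy")
    change = hb_now - state.hb_prev
    if change > TITRATION_TRIGGER:
        return state.current_dose * (1.0 - TITRATION_STEP)
    if change < -TITRATION_TRIGGER:
        return state.current_dose * (1.0 + TITRATION_STEP)
    return state.current_dose


def iron_rule(ferritin: float, tsat: float, iron_on: bool) -> bool:
    """IV-iron status after applying the start/stop triggers.

    Start (or continue) when ferritin < 100 ng/mL or TSAT < 20%; stop when
    ferritin > 800 ng/mL or TSAT > 50%. When triggers contradict, the stop
    rule wins (safety first). No trigger leaves the status unchanged.
    """
    if ferritin < 0:
        raise ValueError("ferritin must be >= 0")
    if not 0 <= tsat <= 100:
        raise ValueError("TSAT must be a percentage in [0, 100]")
    if ferritin > 800 or tsat > 50:
        return False
    if ferritin < 100 or tsat < 20:
        return True
    return iron_on


# ---------------------------------------------------------------------------
# CSR calibration
# ---------------------------------------------------------------------------

def _phase_mean_noise_var(month_sd: float, autocorr: float) -> float:
    """Variance of the 6-month mean of a stationary AR(1) deviation."""
    s2, rho = month_sd ** 2, autocorr
    total = N_MONTHS + 2 * sum((N_MONTHS - k) * rho ** k for k in range(1, N_MONTHS))
    return s2 * total / N_MONTHS ** 2


def calibrate_setpoint_sd(
    target_csr: float,
    phase_mean: float,
    hb_low: float,
    hb_high: float,
    noise_mean_var: float,
) -> float:
    """Setpoint SD giving P(phase-mean Hb in [hb_low, hb_high]) = target_csr.

    Solves for the total phase-mean SD tau with
    Phi((high-mu)/tau) - Phi((low-mu)/tau) = target, then removes the AR(1)
    noise contribution. Targets above what the residual noise permits degrade
    to a zero setpoint SD (the achievable maximum is returned implicitly).
    """
    if not 0 < target_csr < 1:
        raise ValueError("target CSR must be in (0, 1)")
    if not hb_low < phase_mean < hb_high:
        raise ValueError("phase mean must lie inside the target range to calibrate")

    def coverage(tau: float) -> float:
        return norm.cdf((hb_high - phase_mean) / tau) - norm.cdf((hb_low - phase_mean) / tau)

    tau = brentq(lambda t: coverage(t) - target_csr, 1e-9, 100.0)
    return math.sqrt(max(tau ** 2 - noise_mean_var, 0.0))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, arm_index: int, patient_index: int) -> np.random.Generator:
    # independent substream per patient-phase, stable under n_patients changes
    return np.random.default_rng([seed, arm_index, patient_index])


def _arm_setpoint_sd(params: SimulationParams, ap: ArmSimParams) -> float:
    if ap.target_csr is None:
        return ap.phase_hb_sd
    noise_var = _phase_mean_noise_var(params.hb_month_sd, params.hb_autocorr)
    return calibrate_setpoint_sd(
        ap.target_csr, ap.phase_hb_mean, params.hb_low, params.hb_high, noise_var
    )


def _simulate_phase(
    params: SimulationParams,
    arm: Arm,
    patient_index: int,
    setpoint_sd: float,
    start_dose_override: Optional[float] = None,
) -> PatientPhaseRecord:
    ap = params.epob if arm is Arm.EPOB else params.cera
    arm_index = 0 if arm is Arm.EPOB else 1
    rng = _patient_rng(params.seed, arm_index, patient_index)

    z = rng.standard_normal(4 + N_MONTHS)  # one block draw per patient-phase
    setpoint = ap.phase_hb_mean + setpoint_sd * z[0]
    baseline_hb = min(max(ap.baseline_hb_mean + ap.baseline_hb_sd * z[1], 3.5), 19.5)

    if start_dose_override is not None:
        dose = start_dose_override
    else:
        dose = max(ap.mean_dose + ap.dose_sd * z[2], 0.05 * ap.mean_dose)

    state = ProtocolState(agent=arm, current_dose=dose, hb_prev=baseline_hb)
    rho, s = params.hb_autocorr, params.hb_month_sd
    e = s * z[3]  # stationary AR(1) start
    innovation_sd = s * math.sqrt(1.0 - rho ** 2)

    hb, doses, costs = [], [], []
    weeks = params.weeks_per_month
    monthly_price = (
        weeks * ap.unit_price / 1000.0 if arm is Arm.EPOB else ap.unit_price
    )
    for t in range(N_MONTHS):
        target = setpoint + params.dose_response * (state.current_dose - ap.mean_dose)
        hb_now = min(max(target + e, 3.5), 19.5)
        hb.append(hb_now)
        doses.append(state.current_dose)
        costs.append(state.current_dose * monthly_price)
        state.current_dose = titrate(state, hb_now)
        state.hb_prev = hb_now
        e = rho * e + innovation_sd * z[4 + t]

    return PatientPhaseRecord(
        patient_id=f"P{patient_index + 1:03d}",
        arm=arm,
        hb_monthly=tuple(hb),
        dose_monthly=tuple(doses),
        cost_monthly=tuple(costs),
    )


def simulate_cohort(params: Optional[SimulationParams] = None) -> List[PatientPhaseRecord]:
    """Simulate the full crossover cohort: one EpoB and one CERA phase per patient.

    Deterministic for a fixed ``params.seed``; per-patient substreams keep
    each trajectory independent of cohort size and ordering.
    """
    params = params or SimulationParams()
    sd_epob = _arm_setpoint_sd(params, params.epob)
    sd_cera = _arm_setpoint_sd(params, params.cera)
    records: List[PatientPhaseRecord] = []
    for i in range(params.n_patients):
        epob_rec = _simulate_phase(params, Arm.EPOB, i, sd_epob)
        if params.cera_dose_mode == "protocol":
            start = convert_epob_to_cera(epob_rec.dose_monthly[-1])
        else:
            start = None
        records.append(epob_rec)
        records.append(
            _simulate_phase(params, Arm.CERA, i, sd_cera, start_dose_override=start)
        )
    return records
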