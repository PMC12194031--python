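"""Utilities, costs, discounting, and cost-effectiveness summary measures.

Each health state carries an EQ-5D-scale utility and an annual management
cost (primary-care visits, hospitalisations, nephrology reviews) plus an
annual best-supportive-care medication cost; dialysis itself is excluded
from the base case.  Difelikefalin is dosed at 0.5 ug/kg dry body weight
after each haemodialysis session (2.96 sessions/week on average), with
single-use vials rounded up per session.  Costs and QALYs are discounted
at 3.5% a year and accumulated cycle by cycle over the trace, yielding
per-arm totals, incrementals, the ICER, and net monetary benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .severity_transitions import SEVERITY_STATES, STATES

ICER_UNDEFINED = "undefined"
ICER_DOMINANT = "dominant"  # cheaper and more effective
ICER_DOMINATED = "dominated"  # dearer and less effective


@dataclass
class HealthStateValues:
    """Per-state utilities and annual costs (GBP/year).

    BSC cost for the moderate state is set equal to the mild state (lower
    observed antidepressant use in the moderate group would otherwise make
    it cheaper), and the very severe state reuses the severe state's BSC
    cost (the source populations were too small to separate).
    """

    utility: dict = field(
        default_factory=lambda: {
            "none": 0.744,
            "mild": 0.726,
            "moderate": 0.589,
            "severe": 0.595,
            "very_severe": 0.595,
            "transplant": 0.712,
        }
    )
    annual_state_cost: dict = field(
        default_factory=lambda: {
            "none": 3726.0,
            "mild": 3753.0,
            "moderate": 3891.0,
            "severe": 4084.0,
            "very_severe": 4304.0,
        }
    )
    bsc_cost: dict = field(
        default_factory=lambda: {
            "none": 31.98,
            "mild": 42.48,
            "moderate": 42.48,
            "severe": 75.65,
            "very_severe": 75.65,
        }
    )

    def validate(self) -> None:
        for state, u in self.utility.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility[{state}] must be in [0, 1], got {u}")
        for name in ("annual_state_cost", "bsc_cost"):
            for state, c in getattr(self, name).items():
                if c < 0:
                    raise ValueError(f"{name}[{state}] must be >= 0, got {c}")


@dataclass
class DrugCostParams:
    """Difelikefalin acquisition-cost parameters."""

    vial_price: float = 31.90  # GBP
    dose_per_kg: float = 0.5  # micrograms per kg dry body weight
    vial_content: float = 65.0  # micrograms per single-use vial
    sessions_per_week: float = 2.96
    weeks_per_year: float = 52.0

    def validate(self) -> None:
        for name in ("vial_price", "dose_per_kg", "vial_content", "sessions_per_week", "weeks_per_year"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class EconParams:
    """Economic evaluation settings."""

    discount_rate_annual: float = 0.035
    ae_cost_per_event: float = 33.19  # one GP appointment per adverse event
    ae_events_per_patient_year: dict = field(
        default_factory=lambda: {"difelikefalin": 0.10, "bsc": 0.10}
    )
    ae_qaly_loss: float = 0.0
    transplant_cost_once: float = 17000.0  # synthetic default; not published
    posttransplant_annual_cost: float = 5000.0  # synthetic default; not published
    wtp_thresholds: tuple = (30000.0, 40000.0, 50000.0)

    def validate(self) -> None:
        if not 0.0 <= self.discount_rate_annual < 1.0:
            raise ValueError(f"discount_rate_annual must be in [0, 1), got {self.discount_rate_annual}")
        for arm, rate in self.ae_events_per_patient_year.items():
            if rate < 0:
                raise ValueError(f"ae_events_per_patient_year[{arm}] must be >= 0, got {rate}")
        for name in ("ae_cost_per_event", "transplant_cost_once", "posttransplant_annual_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class ArmTotals:
    """Discounted per-patient totals for one arm."""

    total_cost: float
    total_ly: float
    total_qaly: float


@dataclass
class EconResult:
    """Two-arm comparison: totals, incrementals, ICER and NMB."""

    arm_a: ArmTotals  # intervention
    arm_b: ArmTotals  # comparator
    incremental_cost: float = 0.0
    incremental_ly: float = 0.0
    incremental_qaly: float = 0.0
    icer: float | str = ICER_UNDEFINED
    nmb: dict = field(default_factory=dict)


def discount_factor(time_years: float, rate: float) -> float:
    """Standard annual discounting, (1 + rate)^(-t)."""
    if time_years < 0:
        raise ValueError(f"time_years must be >= 0, got {time_years}")
    return (1.0 + rate) ** (-time_years)


def vials_per_session(weight_kg: float, params: DrugCostParams) -> int:
    """Single-use vials needed per dialysis session (rounded up, min 1)."""
    if weight_kg <= 0:
        raise ValueError(f"weight_kg must be > 0, got {weight_kg}")
    return max(1, math.ceil(weight_kg * params.dose_per_kg / params.vial_content))


def annual_drug_cost(params: DrugCostParams, mean_vials_per_session: float) -> float:
    """Yearly difelikefalin acquisition cost for a patient on treatment."""
    return params.vial_price * mean_vials_per_session * params.sessions_per_week * params.weeks_per_year


def mean_vials_from_records(records: pd.DataFrame, params: DrugCostParams) -> float:
    """Cohort mean vials/session (difelikefalin arm dry body weights)."""
    sub = records[records["arm"] == "difelikefalin"]
    if sub.empty:
        raise ValueError("no difelikefalin-arm records")
    return float(np.mean([vials_per_session(w, params) for w in sub["weight_kg"]]))


def accumulate(
    trace: pd.DataFrame,
    values: HealthStateValues,
    drug: DrugCostParams,
    econ: EconParams,
    arm: str,
    mean_vials_per_session: float = 1.0,
    half_cycle_correction: bool = False,
) -> ArmTotals:
    """Discounted cost, life-year and QALY totals for one arm's trace.

    Accrual is per cycle on end-of-cycle occupancy by default; with the
    half-cycle correction the average of start- and end-of-cycle occupancy
    is used and discounting is applied at mid-cycle.  Drug cost accrues on
    the trace's on-treatment occupancy, adverse-event and state costs on
    occupancy, and the one-off transplant cost on within-cycle transplant
    inflow.
    """
    values.validate()
    drug.validate()
    econ.validate()
    missing = set(STATES) - set(trace.columns)
    if missing:
        raise ValueError(f"trace missing state columns {sorted(missing)}")

    sev_idx = list(SEVERITY_STATES)
    state_cost = np.array([values.annual_state_cost[s] + values.bsc_cost[s] for s in sev_idx])
    utility = np.array([values.utility[s] for s in sev_idx] + [values.utility["transplant"], 0.0])
    drug_cost_year = annual_drug_cost(drug, mean_vials_per_session)
    ae_rate = econ.ae_events_per_patient_year.get(arm, 0.0)
    rate = econ.discount_rate_annual

    rows = trace.sort_values("cycle").reset_index(drop=True)
    occ_all = rows[list(STATES)].to_numpy(float)
    times = rows["time_years"].to_numpy(float)
    on_trt_all = rows["on_treatment"].to_numpy(float)
    tx_inflow = rows["tx_inflow"].to_numpy(float)[1:]
    dt = np.diff(times)
    if len(dt) == 0:
        return ArmTotals(0.0, 0.0, 0.0)
    if half_cycle_correction:
        occ = (occ_all[:-1] + occ_all[1:]) / 2.0
        on_trt = (on_trt_all[:-1] + on_trt_all[1:]) / 2.0
        df = (1.0 + rate) ** -(times[:-1] + dt / 2.0)
    else:
        occ = occ_all[1:]
        on_trt = on_trt_all[1:]
        df = (1.0 + rate) ** -times[1:]
    alive = occ[:, :6].sum(axis=1)
    total_ly = float(alive @ (dt * df))
    total_qaly = float((occ @ utility) @ (dt * df))
    cost_per_year = (
        occ[:, :5] @ state_cost
        + occ[:, 5] * econ.posttransplant_annual_cost
        + drug_cost_year * on_trt
        + ae_rate * econ.ae_cost_per_event * alive
    )
    total_cost = float(cost_per_year @ (dt * df)) + float(
        (tx_inflow * econ.transplant_cost_once) @ df
    )
    return ArmTotals(total_cost, total_ly, total_qaly)


def compute_icer(arm_a: ArmTotals, arm_b: ArmTotals, wtp_thresholds=(30000.0, 40000.0, 50000.0)) -> EconResult:
    """Incrementals, ICER (or dominance flag) and NMB of arm A vs arm B."""
    d_cost = arm_a.total_cost - arm_b.total_cost
    d_ly = arm_a.total_ly - arm_b.total_ly
    d_qaly = arm_a.total_qaly - arm_b.total_qaly
    if d_qaly == 0.0:
        icer: float | str = ICER_UNDEFINED
    elif d_qaly > 0 and d_cost <= 0:
        icer = ICER_DOMINANT
    elif d_qaly < 0 and d_cost >= 0:
        icer = ICER_DOMINATED
    else:
        icer = d_cost / d_qaly
    nmb = {float(lam): lam * d_qaly - d_cost for lam in wtp_thresholds}
    return EconResult(arm_a, arm_b, d_cost, d_ly, d_qaly, icer, nmb)


def results_table(result: EconResult) -> pd.DataFrame:
    """Per-arm totals, incrementals and ICER in a compact summary table."""
    icer = result.icer if isinstance(result.icer, str) else round(result.icer, 2)
    return pd.DataFrame(
        {
            "quantity": ["total_cost_gbp", "total_life_years", "total_qalys"],
            "difelikefalin_bsc": [
                result.arm_a.total_cost,
                result.arm_a.total_ly,
                result.arm_a.total_qaly,
            ],
            "bsc": [result.arm_b.total_cost, result.arm_b.total_ly, result.arm_b.total_qaly],
            "incremental": [result.incremental_cost, result.incremental_ly, result.incremental_qaly],
            "icer_gbp_per_qaly": [icer, "", ""],
        }
    )
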