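"""Cohort Markov engine: run-in, responder split, lifetime extrapolation.

The model follows a closed cohort entering in the moderate / severe /
very severe pruritus states.  A 12-week run-in of three 4-week cycles
captures the randomised treatment phase; at week 12 the difelikefalin arm
splits into responders, who stay on treatment (and on the difelikefalin
transition matrix) until transplant or death, and non-responders, who
discontinue and follow best-supportive-care (BSC) dynamics thereafter.
Extrapolation then proceeds in 52-week cycles to the horizon.  Every
cycle is survival-augmented with the year-on-dialysis death/transplant
schedule, severity-specific mortality hazard ratios, and life-table
mortality in the transplant state.  The BSC-dynamics sub-cohorts are
subject to effect waning: their severity mix (conditional on survival) is
pulled linearly back to the baseline mix, reaching it at the waning
horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .severity_transitions import (
    SEVERITY_STATES,
    STATES,
    TransitionMatrix,
    WaningParams,
    apply_waning,
    classify_severity,
)
from .survival_model import CohortDemographics, MortalityHazards, augment_matrix
from .synthetic_cohort import LifeTable, SurvivalSchedule

TRACE_COLUMNS = ["cycle", "time_years", *STATES, "tx_inflow", "on_treatment"]


@dataclass
class ModelSchedule:
    """Cycle structure of the model."""

    run_in_cycles: int = 3
    run_in_cycle_weeks: int = 4
    main_cycle_weeks: int = 52
    horizon_years: int = 42
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValueError(f"horizon_years must be >= 1, got {self.horizon_years}")
        if self.run_in_cycles < 0 or self.run_in_cycle_weeks <= 0 or self.main_cycle_weeks <= 0:
            raise ValueError("cycle counts/lengths must be positive")

    @property
    def run_in_weeks(self) -> int:
        return self.run_in_cycles * self.run_in_cycle_weeks


@dataclass
class ResponderRule:
    """What counts as a clinically meaningful week-12 response.

    ``category_improvement`` (default): improvement by at least
    ``threshold`` severity categories.  ``point_improvement``: improvement
    by at least ``threshold`` 5-D Itch points (5 is the scale's minimal
    clinically important difference).
    """

    criterion: str = "category_improvement"
    threshold: int = 1

    def __post_init__(self) -> None:
        if self.criterion not in ("category_improvement", "point_improvement"):
            raise ValueError(f"unknown responder criterion {self.criterion!r}")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")


@dataclass
class SurvivalInputs:
    """Everything the survival augmentation needs, bundled."""

    schedule: SurvivalSchedule
    hazards: MortalityHazards
    life_table: LifeTable
    demographics: CohortDemographics


def compute_responder_fraction(records: pd.DataFrame, rule: ResponderRule) -> float:
    """Fraction of difelikefalin-arm records responding at week 12."""
    sub = records[records["arm"] == "difelikefalin"]
    if sub.empty:
        raise ValueError("no difelikefalin-arm records to evaluate the responder rule on")
    if rule.criterion == "point_improvement":
        hits = (sub["score_baseline"] - sub["score_week12"]) >= rule.threshold
    else:
        idx = {s: i for i, s in enumerate(SEVERITY_STATES)}
        b = sub["score_baseline"].map(lambda s: idx[classify_severity(int(s))])
        w = sub["score_week12"].map(lambda s: idx[classify_severity(int(s))])
        hits = (b - w) >= rule.threshold
    return float(hits.mean())


def entry_distribution_from_records(records: pd.DataFrame) -> np.ndarray:
    """Baseline severity occupancy (5-vector) of the pooled cohort."""
    idx = {s: i for i, s in enumerate(SEVERITY_STATES)}
    out = np.zeros(5)
    for score in records["score_baseline"]:
        out[idx[classify_severity(int(score))]] += 1.0
    return out / out.sum()


def _cycle_plan(schedule: ModelSchedule):
    """Yield (cycle_index, phase, annual_index, weeks, t_start, t_end)."""
    t = 0.0
    c = 0
    for _ in range(schedule.run_in_cycles):
        c += 1
        weeks = schedule.run_in_cycle_weeks
        yield c, "run_in", 0, weeks, t, t + weeks / 52.0
        t += weeks / 52.0
    for y in range(1, schedule.horizon_years + 1):
        c += 1
        weeks = schedule.main_cycle_weeks
        yield c, "annual", y, weeks, t, t + weeks / 52.0
        t += weeks / 52.0


def _simulate_subcohort(
    entry: np.ndarray,
    runin_matrix: TransitionMatrix,
    annual_matrix: TransitionMatrix,
    schedule: ModelSchedule,
    surv: SurvivalInputs,
    waning: WaningParams | None,
    on_treatment_phases: tuple[str, ...],
) -> pd.DataFrame:
    """Evolve one homogeneous sub-cohort and record its trace.

    When ``waning`` is given, a no-waning companion cohort is evolved in
    parallel under identical survival-augmented matrices; at the end of
    each annual cycle the sub-cohort's severity shape over survivors is
    the waning mixture of the companion's shape and the baseline mix.
    """
    x = np.zeros(7)
    x[:5] = entry
    x_nw = x.copy()  # no-waning companion, supplies the projected severity shape
    rows = [[0, 0.0, *x, 0.0, float(x[:5].sum()) if "run_in" in on_treatment_phases else 0.0]]
    for c, phase, y, weeks, t_start, t_end in _cycle_plan(schedule):
        year = max(1, math.ceil(t_end - 1e-9))  # year on dialysis for the schedule
        matrix = runin_matrix if phase == "run_in" else annual_matrix
        A = augment_matrix(
            matrix,
            year,
            surv.schedule,
            surv.hazards,
            weeks,
            surv.life_table,
            surv.demographics,
            surv.demographics.start_age_years + t_start,
        )
        tx_inflow = float(x[:5] @ A[:5, 5])
        x = x @ A
        x_nw = x_nw @ A
        if waning is not None and phase == "annual":
            sev_mass = x[:5].sum()
            nw_mass = x_nw[:5].sum()
            if sev_mass > 0 and nw_mass > 0:
                shape = apply_waning(x_nw[:5] / nw_mass, waning, y)
                x[:5] = shape * sev_mass
        on_trt = float(x[:5].sum()) if phase in on_treatment_phases else 0.0
        rows.append([c, t_end, *x, tx_inflow, on_trt])
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def _combine(traces_weights: list[tuple[pd.DataFrame, float]], arm: str) -> pd.DataFrame:
    base = traces_weights[0][0][["cycle", "time_years"]].copy()
    vals = sum(w * tr[[*STATES, "tx_inflow", "on_treatment"]].to_numpy() for tr, w in traces_weights)
    out = pd.concat([base, pd.DataFrame(vals, columns=[*STATES, "tx_inflow", "on_treatment"])], axis=1)
    out["arm"] = arm
    return out


def run_markov(
    entry_distribution: np.ndarray,
    matrices: dict[str, TransitionMatrix],
    schedule: ModelSchedule,
    surv: SurvivalInputs,
    waning: WaningParams | None,
    responder_fraction: float,
) -> dict[str, pd.DataFrame]:
    """Run both arms and return their cohort traces.

    Parameters
    ----------
    entry_distribution : ndarray, shape (5,)
        Baseline severity occupancy; mass only on moderate-or-worse states.
    matrices : dict
        Per-arm severity ``TransitionMatrix`` keyed ``"difelikefalin"`` /
        ``"placebo"`` (the placebo matrix carries the BSC dynamics).
    waning : WaningParams
        Waning applied to every sub-cohort on BSC dynamics.
    responder_fraction : float
        Week-12 responder fraction r in the difelikefalin arm.  The arm's
        trace is the mixture of a responder sub-cohort (difelikefalin
        matrix throughout, no waning, on treatment until transplant or
        death) weighted r and a non-responder sub-cohort (difelikefalin
        matrix during the run-in they were treated through, BSC dynamics
        with waning afterwards) weighted 1 - r.

    Returns
    -------
    dict
        ``{"difelikefalin": trace, "bsc": trace}`` -- DataFrames with one
        row per cycle (plus the entry row), columns for each state's
        occupancy, the within-cycle transplant inflow, and the occupancy
        accruing drug cost.
    """
    entry = np.asarray(entry_distribution, dtype=float)
    if entry.shape != (5,):
        raise ValueError("entry_distribution must have 5 severity entries")
    if not np.isclose(entry.sum(), 1.0, atol=1e-10):
        raise ValueError("entry_distribution must sum to 1")
    if entry[:2].sum() > 1e-12:
        raise ValueError("entry_distribution can have mass only on moderate/severe/very_severe")
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError(f"responder_fraction must be in [0, 1], got {responder_fraction}")

    m_dfk = matrices["difelikefalin"]
    m_bsc = matrices["placebo"]

    bsc = _simulate_subcohort(entry, m_bsc, m_bsc, schedule, surv, waning, ())
    bsc["arm"] = "bsc"

    r = responder_fraction
    resp = _simulate_subcohort(
        entry, m_dfk, m_dfk, schedule, surv, None, ("run_in", "annual")
    )
    nonresp = _simulate_subcohort(entry, m_dfk, m_bsc, schedule, surv, waning, ("run_in",))
    dfk = _combine([(resp, r), (nonresp, 1.0 - r)], "difelikefalin")

    for tr in (dfk, bsc):
        _validate_trace(tr)
    return {"difelikefalin": dfk, "bsc": bsc}


def _validate_trace(trace: pd.DataFrame) -> None:
    occ = trace[list(STATES)].to_numpy()
    if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10):
        raise AssertionError("trace rows must sum to 1 within 1e-10")
    death = trace["death"].to_numpy()
    if (np.diff(death) < -1e-12).any():
        raise AssertionError("death occupancy must be non-decreasing")


def write_trace(trace: pd.DataFrame, path) -> None:
    trace.to_csv(path, index=False, float_format="%.17g")
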