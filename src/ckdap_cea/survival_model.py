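"""Death and transplant dynamics for the cohort model.

Patients on dialysis face a year-on-dialysis-dependent annual probability
of death and of transplant.  Pruritus severity raises the death hazard:
published Cox hazard ratios of 1.11 / 1.02 / 1.24 for moderately / very
much / extremely bothered patients are mapped to the moderate / severe /
very severe states (the sequence is applied as published, not smoothed).
Hazard ratios act on the rate scale, p' = 1 - (1 - p)^HR, which keeps
probabilities in [0, 1] for any HR > 0.  After a transplant, mortality
follows an age- and sex-adjusted life table; the transplant state is
otherwise absorbing (a transplant is treated as definitive for pruritus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .severity_transitions import SEVERITY_STATES, STATES, TransitionMatrix
from .synthetic_cohort import LifeTable, SurvivalSchedule


@dataclass
class MortalityHazards:
    """Severity-specific all-cause mortality hazard ratios (vs no pruritus)."""

    hr_none: float = 1.0
    hr_mild: float = 1.0
    hr_moderate: float = 1.11
    hr_severe: float = 1.02
    hr_very_severe: float = 1.24

    def __post_init__(self) -> None:
        for name in ("hr_none", "hr_mild", "hr_moderate", "hr_severe", "hr_very_severe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def by_state(self) -> np.ndarray:
        return np.array(
            [self.hr_none, self.hr_mild, self.hr_moderate, self.hr_severe, self.hr_very_severe]
        )


@dataclass
class CohortDemographics:
    start_age_years: float = 59.0
    female_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.start_age_years < 18:
            raise ValueError(f"start_age_years must be >= 18, got {self.start_age_years}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError(f"female_fraction must be in [0, 1], got {self.female_fraction}")


def severity_adjusted_death_prob(p_base: float, hr: float) -> float:
    """Apply a hazard ratio to an annual death probability on the rate scale."""
    if not 0.0 <= p_base <= 1.0:
        raise ValueError(f"p_base must be in [0, 1], got {p_base}")
    if hr <= 0:
        raise ValueError(f"hr must be > 0, got {hr}")
    if p_base == 1.0 and hr != 1.0:
        raise ValueError("p_base = 1 cannot be hazard-adjusted")
    return 1.0 - (1.0 - p_base) ** hr


def per_cycle_probability(p_annual: float, cycle_weeks: float) -> float:
    """Convert an annual probability to a cycle of ``cycle_weeks`` weeks.

    Constant-rate conversion: 1 - (1 - p)^(weeks/52), so 13 four-week
    cycles compound back to the annual probability.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must be in [0, 1], got {p_annual}")
    if cycle_weeks <= 0:
        raise ValueError(f"cycle_weeks must be > 0, got {cycle_weeks}")
    return 1.0 - (1.0 - p_annual) ** (cycle_weeks / 52.0)


def posttransplant_death_prob(age: float, demographics: CohortDemographics, life_table: LifeTable) -> float:
    """Annual post-transplant mortality: sex-mixture of life-table q at integer age."""
    return life_table.q_mixed(age, demographics.female_fraction)


def augment_matrix(
    sev_matrix: TransitionMatrix,
    year: int,
    schedule: SurvivalSchedule,
    hazards: MortalityHazards,
    cycle_weeks: float,
    life_table: LifeTable,
    demographics: CohortDemographics,
    age_years: float,
) -> np.ndarray:
    """Build the full 7-state per-cycle matrix from a 5-state severity block.

    For each severity row the per-cycle death probability (hazard-adjusted
    annual schedule value, converted to the cycle length) and the
    per-cycle transplant probability compete by proportionally scaling
    the severity block with the remaining mass.  The transplant row stays
    in transplant except for life-table death at the cohort's current
    age; death is absorbing.

    Parameters
    ----------
    year : int
        Year on dialysis used to index the survival schedule (clamps at 10).
    age_years : float
        Current cohort age, for post-transplant life-table mortality.

    Returns
    -------
    ndarray, shape (7, 7)
        Row-stochastic matrix over ``STATES``.
    """
    n = len(STATES)
    full = np.zeros((n, n))
    p_death_annual = schedule.p_death(year)
    p_tx_annual = schedule.p_transplant(year)
    p_tx_cycle = per_cycle_probability(p_tx_annual, cycle_weeks)
    for i, hr in enumerate(hazards.by_state()):
        p_death_cycle = per_cycle_probability(
            severity_adjusted_death_prob(p_death_annual, hr), cycle_weeks
        )
        if p_death_cycle + p_tx_cycle >= 1.0:
            raise ValueError(
                f"per-cycle death + transplant mass >= 1 for state {SEVERITY_STATES[i]!r}"
            )
        full[i, :5] = sev_matrix.probs[i] * (1.0 - p_death_cycle - p_tx_cycle)
        full[i, 5] = p_tx_cycle
        full[i, 6] = p_death_cycle
    q_tx = per_cycle_probability(
        posttransplant_death_prob(age_years, demographics, life_table), cycle_weeks
    )
    full[5, 5] = 1.0 - q_tx
    full[5, 6] = q_tx
    full[6, 6] = 1.0
    return full
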