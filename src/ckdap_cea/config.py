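"""Configuration assembly, validation, and end-to-end orchestration.

A single :class:`ModelConfig` collects every tunable input of the
analysis.  It can be built from a nested key-value YAML file (unknown
keys are rejected with the offending field named) or used with its
packaged defaults, which run the full pipeline on synthetic data.  The
orchestration entry point :func:`run_base_case` chains the stages:
generate the cohort, estimate per-arm transition matrices, compute the
responder fraction, run the Markov engine, and attach economics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .economics import (
    ArmTotals,
    DrugCostParams,
    EconParams,
    EconResult,
    HealthStateValues,
    accumulate,
    compute_icer,
    mean_vials_from_records,
)
from .markov_engine import (
    ModelSchedule,
    ResponderRule,
    SurvivalInputs,
    compute_responder_fraction,
    entry_distribution_from_records,
    run_markov,
)
from .severity_transitions import TransitionMatrix, WaningParams, estimate_transition_matrix
from .survival_model import CohortDemographics, MortalityHazards
from .synthetic_cohort import (
    CohortGenParams,
    ConfigurationError,
    default_life_table,
    default_survival_schedule,
    generate_cohort,
    load_life_table,
    load_survival_schedule,
)

logger = logging.getLogger("ckdap_cea")


@dataclass
class ModelConfig:
    """Every input of the cost-utility analysis, with packaged defaults."""

    cohort: CohortGenParams = field(default_factory=CohortGenParams)
    schedule: ModelSchedule = field(default_factory=ModelSchedule)
    responder_rule: ResponderRule = field(default_factory=ResponderRule)
    hazards: MortalityHazards = field(default_factory=MortalityHazards)
    demographics: CohortDemographics = field(default_factory=CohortDemographics)
    values: HealthStateValues = field(default_factory=HealthStateValues)
    drug: DrugCostParams = field(default_factory=DrugCostParams)
    econ: EconParams = field(default_factory=EconParams)
    waning_horizon_years: float = 10.0
    survival_schedule_path: str | None = None  # None -> packaged synthetic fixture
    life_table_path: str | None = None

    def validate(self) -> None:
        self.cohort.validate()
        self.values.validate()
        self.drug.validate()
        self.econ.validate()
        if self.waning_horizon_years <= 0:
            raise ConfigurationError(
                f"waning_horizon_years must be > 0, got {self.waning_horizon_years}"
            )

    def survival_inputs(self) -> SurvivalInputs:
        sched = (
            load_survival_schedule(self.survival_schedule_path)
            if self.survival_schedule_path
            else default_survival_schedule()
        )
        lt = load_life_table(self.life_table_path) if self.life_table_path else default_life_table()
        return SurvivalInputs(sched, self.hazards, lt, self.demographics)


_SECTIONS = {
    "cohort": (CohortGenParams, "cohort"),
    "schedule": (ModelSchedule, "schedule"),
    "responder_rule": (ResponderRule, "responder_rule"),
    "hazards": (MortalityHazards, "hazards"),
    "demographics": (CohortDemographics, "demographics"),
    "health_state_values": (HealthStateValues, "values"),
    "drug_cost": (DrugCostParams, "drug"),
    "economics": (EconParams, "econ"),
}


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown field(s) {sorted(unknown)} in section {section!r}")
    try:
        obj = cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid section {section!r}: {exc}") from exc
    defaulted = names - set(data)
    if defaulted:
        logger.info("section %s: defaulted fields %s", section, sorted(defaulted))
    return obj


def config_from_dict(data: dict) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a nested mapping."""
    data = dict(data or {})
    kwargs = {}
    for key, (cls, attr) in _SECTIONS.items():
        if key in data:
            section = data.pop(key)
            if not isinstance(section, dict):
                raise ConfigurationError(f"section {key!r} must be a mapping")
            kwargs[attr] = _build_section(cls, section, key)
    for scalar in ("waning_horizon_years", "survival_schedule_path", "life_table_path"):
        if scalar in data:
            kwargs[scalar] = data.pop(scalar)
    if data:
        raise ConfigurationError(f"unknown top-level field(s) {sorted(data)}")
    cfg = ModelConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> ModelConfig:
    """Load a nested key-value YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def default_config() -> ModelConfig:
    cfg = ModelConfig()
    cfg.validate()
    return cfg


@dataclass
class BaseCaseOutput:
    """Everything the deterministic pipeline produces."""

    config: ModelConfig
    records: pd.DataFrame
    matrices: dict[str, TransitionMatrix]
    entry_distribution: np.ndarray
    responder_fraction: float
    mean_vials_per_session: float
    traces: dict[str, pd.DataFrame]
    totals: dict[str, ArmTotals]
    result: EconResult


def run_base_case(
    config: ModelConfig,
    seed: int | None = None,
    matrices: dict[str, TransitionMatrix] | None = None,
    responder_fraction: float | None = None,
    surv: SurvivalInputs | None = None,
) -> BaseCaseOutput:
    """Run the deterministic pipeline end to end.

    Parameters
    ----------
    seed : int, optional
        Overrides ``config.cohort.seed`` for cohort generation.
    matrices, responder_fraction, surv : optional
        Pre-computed stage outputs (used by the sensitivity analyses to
        resample or perturb mid-pipeline quantities without regenerating
        the cohort).
    """
    config.validate()
    cohort_params = config.cohort
    if seed is not None:
        cohort_params = dataclasses.replace(cohort_params, seed=seed)
    logger.info("generating cohort: n_per_arm=%d seed=%d", cohort_params.n_per_arm, cohort_params.seed)
    records = generate_cohort(cohort_params)

    if matrices is None:
        matrices = {
            arm: estimate_transition_matrix(records, arm) for arm in ("difelikefalin", "placebo")
        }
    entry = entry_distribution_from_records(records)
    if responder_fraction is None:
        responder_fraction = compute_responder_fraction(records, config.responder_rule)
    logger.info("responder fraction (difelikefalin arm): %.4f", responder_fraction)

    waning = WaningParams(entry, config.waning_horizon_years)
    if surv is None:
        surv = config.survival_inputs()
    traces = run_markov(entry, matrices, config.schedule, surv, waning, responder_fraction)

    mean_vials = mean_vials_from_records(records, config.drug)
    totals = {
        arm: accumulate(
            traces[arm],
            config.values,
            config.drug,
            config.econ,
            arm,
            mean_vials,
            config.schedule.half_cycle_correction,
        )
        for arm in ("difelikefalin", "bsc")
    }
    result = compute_icer(totals["difelikefalin"], totals["bsc"], config.econ.wtp_thresholds)
    logger.info(
        "base case: d_cost=%.2f d_qaly=%.4f icer=%s",
        result.incremental_cost,
        result.incremental_qaly,
        result.icer,
    )
    return BaseCaseOutput(
        config,
        records,
        matrices,
        entry,
        responder_fraction,
        mean_vials,
        traces,
        totals,
        result,
    )
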