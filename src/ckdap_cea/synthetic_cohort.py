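"""Synthetic patient-level cohort generator and fixture-table loaders.

The analysis needs three data inputs that cannot ship with the package as
real data: pooled patient-level trial records, the annual death/transplant
schedule for the in-centre haemodialysis population, and a sex-stratified
life table for post-transplant mortality.  This module generates the first
from a seeded statistical model and loads the other two from packaged
plain-text fixtures (both clearly labelled synthetic).

The cohort model: baseline total 5-D Itch scores are a discretised normal
truncated to [12, 25] (entry restricted to moderate-or-worse pruritus);
the week-12 score is baseline plus an integer-rounded normal change whose
mean depends on arm and baseline severity stratum.  The default change
means are calibrated so that the two arms' proportions achieving a
>= 5-point improvement reproduce the trial-reported 52.1% (difelikefalin)
and 42.3% (placebo).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .severity_transitions import SCORE_MAX, classify_severity

ARMS = ("difelikefalin", "placebo")
SEXES = ("female", "male")

ENTRY_SCORE_MIN = 12  # moderate band starts at 12

# Default week-12 mean score change (negative = improvement), by arm and
# baseline severity stratum.  Calibrated jointly with change_sd = 5 so the
# expected >= 5-point response proportions are 52.1% / 42.3%.
DEFAULT_CHANGE_MEANS: dict[str, dict[str, float]] = {
    "difelikefalin": {"moderate": -4.08, "severe": -5.08, "very_severe": -6.08},
    "placebo": {"moderate": -3.18, "severe": -3.68, "very_severe": -4.18},
}


class ConfigurationError(ValueError):
    """Raised for invalid generator or loader parameters; names the field."""


@dataclass
class CohortGenParams:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_per_arm : int
        Records generated per arm.
    baseline_mean, baseline_sd : float
        Mean/SD of the latent normal behind the discretised truncated
        baseline score distribution (score units).
    change_mean_by_arm_and_stratum : dict
        Week-12 mean score change keyed by arm then baseline stratum.
    change_sd : float
        SD of the week-12 change draw (score units).
    response_threshold : int
        Score-point improvement defining treatment response (the 5-point
        threshold is the recognised minimal clinically important
        difference for the 5-D Itch scale).
    female_fraction : float
        Proportion of female patients.
    weight_mean_kg, weight_sd_kg : float
        Dry body weight distribution (normal, truncated at 30 kg).
    seed : int
        Single seed governing every draw.
    """

    n_per_arm: int = 500
    baseline_mean: float = 18.0
    baseline_sd: float = 3.0
    change_mean_by_arm_and_stratum: dict = field(
        default_factory=lambda: {a: dict(d) for a, d in DEFAULT_CHANGE_MEANS.items()}
    )
    change_sd: float = 5.0
    response_threshold: int = 5
    female_fraction: float = 0.4
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ConfigurationError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        for name in ("baseline_sd", "change_sd", "weight_sd_kg"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError(f"female_fraction must be in [0, 1], got {self.female_fraction}")
        if self.weight_mean_kg <= 0:
            raise ConfigurationError(f"weight_mean_kg must be > 0, got {self.weight_mean_kg}")
        if self.response_threshold <= 0:
            raise ConfigurationError(f"response_threshold must be > 0, got {self.response_threshold}")
        for arm in ARMS:
            if arm not in self.change_mean_by_arm_and_stratum:
                raise ConfigurationError(f"change_mean_by_arm_and_stratum missing arm {arm!r}")


def _discretised_truncated_baseline(params: CohortGenParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """Integer baseline scores from a discretised normal truncated to [12, 25]."""
    from scipy.stats import norm

    ks = np.arange(ENTRY_SCORE_MIN, SCORE_MAX + 1)
    p = norm.cdf(ks + 0.5, params.baseline_mean, params.baseline_sd) - norm.cdf(
        ks - 0.5, params.baseline_mean, params.baseline_sd
    )
    p = p / p.sum()
    return rng.choice(ks, size=n, p=p)


def generate_cohort(params: CohortGenParams) -> pd.DataFrame:
    """Generate a seeded two-arm synthetic cohort.

    Returns a DataFrame with one row per patient and columns
    ``patient_id, arm, sex, weight_kg, score_baseline, score_week12``.
    Fully reproducible from ``params.seed``; two calls with identical
    parameters yield identical frames.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    frames = []
    for arm in ARMS:
        n = params.n_per_arm
        baseline = _discretised_truncated_baseline(params, rng, n)
        strata = np.array([classify_severity(int(b)) for b in baseline])
        means = np.array([params.change_mean_by_arm_and_stratum[arm][s] for s in strata])
        change = np.rint(rng.normal(means, params.change_sd)).astype(int)
        week12 = np.clip(baseline + change, 5, SCORE_MAX)
        sex = np.where(rng.random(n) < params.female_fraction, "female", "male")
        # dry body weight: normal truncated below at 30 kg by redrawing
        weight = rng.normal(params.weight_mean_kg, params.weight_sd_kg, n)
        bad = weight < 30.0
        while bad.any():
            weight[bad] = rng.normal(params.weight_mean_kg, params.weight_sd_kg, bad.sum())
            bad = weight < 30.0
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"{arm[:3].upper()}-{i:05d}" for i in range(n)],
                    "arm": arm,
                    "sex": sex,
                    "weight_kg": weight,
                    "score_baseline": baseline,
                    "score_week12": week12,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def response_fraction(records: pd.DataFrame, arm: str, threshold: int = 5) -> float:
    """Fraction of an arm improving by at least ``threshold`` 5-D Itch points."""
    sub = records[records["arm"] == arm]
    if sub.empty:
        raise ValueError(f"no records for arm {arm!r}")
    return float(((sub["score_baseline"] - sub["score_week12"]) >= threshold).mean())


def write_cohort(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# fixture tables: survival schedule and life table
# ---------------------------------------------------------------------------


@dataclass
class SurvivalSchedule:
    """Annual death/transplant probabilities by year on dialysis.

    Defined for years 1-10; queries beyond year 10 return the year-10 row
    (all later years are assumed identical to year 10).
    """

    table: pd.DataFrame  # columns: year, p_death, p_transplant

    def __post_init__(self) -> None:
        t = self.table
        if sorted(t["year"]) != list(range(1, 11)):
            raise ConfigurationError("survival schedule must contain exactly years 1-10")
        for col in ("p_death", "p_transplant"):
            if ((t[col] < 0) | (t[col] > 1)).any():
                raise ConfigurationError(f"{col} outside [0, 1] in survival schedule")
        if ((t["p_death"] + t["p_transplant"]) > 1 + 1e-12).any():
            raise ConfigurationError("p_death + p_transplant > 1 in survival schedule")
        self.table = t.sort_values("year").reset_index(drop=True)
        self._p_death = self.table["p_death"].to_numpy(float)
        self._p_transplant = self.table["p_transplant"].to_numpy(float)

    def p_death(self, year: int) -> float:
        return float(self._p_death[min(max(int(year), 1), 10) - 1])

    def p_transplant(self, year: int) -> float:
        return float(self._p_transplant[min(max(int(year), 1), 10) - 1])


@dataclass
class LifeTable:
    """Sex-stratified annual mortality q(age); ages clamp to the table range."""

    table: pd.DataFrame  # columns: age, sex, q

    def __post_init__(self) -> None:
        t = self.table
        if ((t["q"] < 0) | (t["q"] > 1)).any():
            raise ConfigurationError("life table q outside [0, 1]")
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_sex:
            raise ConfigurationError(f"life table has unknown sex values {bad_sex}")
        self._by_sex = {}
        for s in SEXES:
            sub = t[t["sex"] == s].sort_values("age")
            if sub.empty:
                raise ConfigurationError(f"life table has no rows for sex {s!r}")
            self._by_sex[s] = (sub["age"].to_numpy(int), sub["q"].to_numpy(float))

    def q(self, age: float, sex: str) -> float:
        ages, qs = self._by_sex[sex]
        a = min(max(int(age), ages[0]), ages[-1])
        return float(qs[np.searchsorted(ages, a)])

    def q_mixed(self, age: float, female_fraction: float) -> float:
        """Sex-mixture mortality f*q_female + (1-f)*q_male at integer age."""
        f = female_fraction
        return f * self.q(age, "female") + (1.0 - f) * self.q(age, "male")


def load_survival_schedule(path) -> SurvivalSchedule:
    """Load and validate an annual death/transplant schedule from text."""
    df = pd.read_csv(path)
    missing = {"year", "p_death", "p_transplant"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"survival schedule missing columns {sorted(missing)}")
    return SurvivalSchedule(df[["year", "p_death", "p_transplant"]])


def load_life_table(path) -> LifeTable:
    """Load and validate a sex-stratified life table from text."""
    df = pd.read_csv(path)
    missing = {"age", "sex", "q"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"life table missing columns {sorted(missing)}")
    return LifeTable(df[["age", "sex", "q"]])


def packaged_fixture(name: str):
    """Path-like handle to a packaged data fixture."""
    return resources.files("ckdap_cea").joinpath("data", name)


def default_survival_schedule() -> SurvivalSchedule:
    return load_survival_schedule(packaged_fixture("synthetic_survival_schedule.csv"))


def default_life_table() -> LifeTable:
    return load_life_table(packaged_fixture("synthetic_life_table.csv"))
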