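"""Severity states, score-to-state classification, transition-matrix
estimation, and the treatment-effect waning rule.

Pruritus severity is graded from the total 5-D Itch score (integer 5-25,
higher = worse itch) into five bands.  Two further states -- kidney
transplant and death -- are appended by the survival model; within this
module all matrices live on the 5-state severity block.

The per-cycle severity transition matrix for an arm is estimated from
patient-level records: within each baseline-severity stratum the mean
week-12 score change is computed, and each patient's destination
probabilities are the mass of a normal distribution (centred at their
baseline score plus the stratum mean change) falling into each severity
band.  Band boundaries sit at half-integers because scores are integers
(continuity correction).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

# Ordered severity states (least to most severe), then the two states the
# survival model appends.  Order is load-bearing everywhere downstream.
SEVERITY_STATES: tuple[str, ...] = ("none", "mild", "moderate", "severe", "very_severe")
STATES: tuple[str, ...] = SEVERITY_STATES + ("transplant", "death")
ENTRY_STATES: tuple[str, ...] = ("moderate", "severe", "very_severe")

SCORE_MIN, SCORE_MAX = 5, 25

# Upper score bound of each band: none <=8, mild 9-11, moderate 12-17,
# severe 18-21, very severe >=22.
_BAND_UPPER = {"none": 8, "mild": 11, "moderate": 17, "severe": 21, "very_severe": 25}

# Half-integer band edges used for normal-mass integration over bands.
BAND_EDGES = np.array([-np.inf, 8.5, 11.5, 17.5, 21.5, np.inf])

# Representative score used when a change model must be applied to a band
# never occupied at entry (band midpoint).
BAND_MIDPOINT = {"none": 6.5, "mild": 10.0, "moderate": 14.5, "severe": 19.5, "very_severe": 23.5}


class ScoreRangeError(ValueError):
    """Raised for a 5-D Itch total outside the instrument's 5-25 range."""


class EstimationError(ValueError):
    """Raised when a transition row cannot be estimated for a stratum."""


def classify_severity(score: int) -> str:
    """Map a total 5-D Itch score to its severity band.

    Parameters
    ----------
    score : int
        Total 5-D Itch score, in [5, 25].

    Returns
    -------
    str
        One of ``SEVERITY_STATES``.
    """
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ScoreRangeError(f"5-D Itch total {score!r} outside valid range [{SCORE_MIN}, {SCORE_MAX}]")
    for state, upper in _BAND_UPPER.items():
        if score <= upper:
            return state
    raise AssertionError("unreachable")


def band_masses(mean: float, sd: float) -> np.ndarray:
    """Probability mass of Normal(mean, sd) in each severity band.

    Tail mass below 8.5 goes to 'none' and above 21.5 to 'very_severe'.
    In the degenerate limit sd -> 0 the whole mass lands in the band
    containing ``mean``.
    """
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        out = np.zeros(5)
        idx = int(np.searchsorted(BAND_EDGES, mean, side="left")) - 1
        out[min(max(idx, 0), 4)] = 1.0
        return out
    cdf = norm.cdf(BAND_EDGES, loc=mean, scale=sd)
    masses = np.diff(cdf)
    return masses / masses.sum()


@dataclass
class TransitionMatrix:
    """Row-stochastic 5x5 matrix over the severity block.

    Attributes
    ----------
    probs : ndarray, shape (5, 5)
        Row i gives destination probabilities from ``SEVERITY_STATES[i]``.
    cycle_length_weeks : int
        Cycle length the matrix is applied over (4 during run-in, 52 after).
    """

    probs: np.ndarray
    cycle_length_weeks: int = 4

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (5, 5):
            raise ValueError(f"severity matrix must be 5x5, got {self.probs.shape}")
        if (self.probs < -1e-15).any() or (self.probs > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = self.probs.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-12):
            raise ValueError(f"rows must sum to 1 within 1e-12, got {rowsums}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(SEVERITY_STATES), columns=list(SEVERITY_STATES))

    def write(self, path) -> None:
        """Serialise to delimiter-separated text with state-name headers."""
        df = self.to_frame()
        df.index.name = "from_state"
        # repr-precision floats round-trip bit-identically
        df.to_csv(path, float_format="%.17g")

    @classmethod
    def read(cls, path, cycle_length_weeks: int = 4) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if list(df.index) != list(SEVERITY_STATES) or list(df.columns) != list(SEVERITY_STATES):
            raise ValueError("matrix file must carry the five severity states in canonical order")
        return cls(df.to_numpy(dtype=float), cycle_length_weeks)


def pooled_change_sd(records: pd.DataFrame) -> float:
    """Pooled within-stratum sample SD of week-12 score changes."""
    ss, dof = 0.0, 0
    for _, grp in records.groupby("baseline_severity"):
        d = grp["score_week12"] - grp["score_baseline"]
        n = len(d)
        if n >= 2:
            ss += d.var(ddof=1) * (n - 1)
            dof += n - 1
    if dof == 0:
        raise EstimationError("cannot pool a change SD: no stratum has >= 2 records")
    return float(np.sqrt(ss / dof))


def estimate_transition_matrix(
    records: pd.DataFrame,
    arm: str,
    change_sd: float | None = None,
    cycle_length_weeks: int = 4,
) -> TransitionMatrix:
    """Estimate the per-cycle severity transition matrix for one arm.

    For each entry stratum s the stratum mean score change over the run-in
    is computed; each record's destination probabilities are the normal
    band masses of N(score_baseline + mean_change_s, change_sd), and the
    stratum row is their average.  The 'none' and 'mild' rows (states
    unoccupied at entry) reuse the moderate stratum's change model applied
    at the band midpoint, so patients who improve into those states still
    have onward dynamics.

    Parameters
    ----------
    records : DataFrame
        Patient-level records with columns arm, score_baseline, score_week12.
    arm : str
        Which arm's records to use.
    change_sd : float, optional
        SD of the change model.  Defaults to the pooled within-stratum
        sample SD of the observed changes.
    """
    sub = records[records["arm"] == arm].copy()
    if sub.empty:
        raise EstimationError(f"no records for arm {arm!r}")
    sub["baseline_severity"] = [classify_severity(int(s)) for s in sub["score_baseline"]]
    if change_sd is None:
        change_sd = pooled_change_sd(sub)

    mean_change: dict[str, float] = {}
    rows: dict[str, np.ndarray] = {}
    for stratum, grp in sub.groupby("baseline_severity"):
        delta = float((grp["score_week12"] - grp["score_baseline"]).mean())
        mean_change[stratum] = delta
        per_record = np.stack([band_masses(b + delta, change_sd) for b in grp["score_baseline"]])
        rows[stratum] = per_record.mean(axis=0)

    if "moderate" not in mean_change:
        # fall back to the least severe occupied stratum
        for cand in ("severe", "very_severe"):
            if cand in mean_change:
                fallback = cand
                break
        else:
            raise EstimationError("no occupied entry stratum to borrow a change model from")
    else:
        fallback = "moderate"

    matrix = np.zeros((5, 5))
    for i, state in enumerate(SEVERITY_STATES):
        if state in rows:
            matrix[i] = rows[state]
        else:
            if state in ENTRY_STATES:
                raise EstimationError(f"entry stratum {state!r} is empty for arm {arm!r} and has no fallback")
            matrix[i] = band_masses(BAND_MIDPOINT[state] + mean_change[fallback], change_sd)
    return TransitionMatrix(matrix, cycle_length_weeks)


@dataclass
class WaningParams:
    """Linear return of the BSC arm to its baseline severity mix.

    The treatment-extrapolation assumption is that any placebo/BSC benefit
    fades, with the cohort's severity distribution back at its baseline
    mix by ``waning_horizon_years``.  The path between is linear in years.
    """

    baseline_distribution: np.ndarray
    waning_horizon_years: float = 10.0

    def __post_init__(self) -> None:
        self.baseline_distribution = np.asarray(self.baseline_distribution, dtype=float)
        if self.baseline_distribution.shape != (5,):
            raise ValueError("baseline_distribution must have 5 severity entries")
        if not np.isclose(self.baseline_distribution.sum(), 1.0, atol=1e-10):
            raise ValueError("baseline_distribution must sum to 1")
        if self.baseline_distribution[:2].sum() > 1e-12:
            raise ValueError("entry baseline distribution can have no mass on none/mild")
        if self.waning_horizon_years <= 0:
            raise ValueError("waning_horizon_years must be > 0")

    def weight(self, year: float) -> float:
        """Waning weight w(y) = min(y / horizon, 1)."""
        return min(max(float(year), 0.0) / self.waning_horizon_years, 1.0)


def apply_waning(no_waning_dist: np.ndarray, waning: WaningParams, year: float) -> np.ndarray:
    """Mix the no-waning severity projection back toward baseline.

    Operates on the severity block conditional on survival: both the input
    and the result are probability vectors over the 5 severity states.
    At year 0 the projection is returned unchanged; at or beyond the
    waning horizon the baseline distribution is returned exactly.
    """
    d = np.asarray(no_waning_dist, dtype=float)
    if d.shape != (5,):
        raise ValueError("severity distribution must have 5 entries")
    if not np.isclose(d.sum(), 1.0, atol=1e-9):
        raise ValueError("severity distribution must sum to 1")
    w = waning.weight(year)
    return (1.0 - w) * d + w * waning.baseline_distribution
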