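"""Deterministic (one-way) and probabilistic sensitivity analyses.

The one-way analysis perturbs each scalar input to a low and a high value
(default +/- 20% of base), re-runs the full deterministic pipeline, and
ranks parameters by the absolute swing in the ICER (tornado ordering).

The probabilistic analysis assigns each parameter class its conventional
distribution -- utilities beta (moment-matched), costs gamma, hazard
ratios log-normal, transition-matrix rows Dirichlet, schedule
probabilities beta -- with every distribution centred on the base value.
Each iteration re-evaluates the whole model; outputs are the iteration
table, mean incrementals, the cost-effectiveness plane, and the
cost-effectiveness acceptability curve (CEAC): the fraction of iterations
with positive net monetary benefit at each willingness-to-pay threshold.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BaseCaseOutput, ModelConfig, run_base_case
from .economics import ICER_UNDEFINED, accumulate, compute_icer
from .markov_engine import SurvivalInputs, run_markov
from .severity_transitions import TransitionMatrix, WaningParams
from .synthetic_cohort import ConfigurationError, SurvivalSchedule

logger = logging.getLogger("ckdap_cea")

# ---------------------------------------------------------------------------
# one-way DSA
# ---------------------------------------------------------------------------

# (dotted path, admissible domain) of the scalar inputs varied by default
DEFAULT_DSA_PARAMETERS: list[tuple[str, tuple[float, float]]] = (
    [(f"values.utility.{s}", (0.0, 1.0)) for s in ("none", "mild", "moderate", "severe", "very_severe", "transplant")]
    + [(f"values.annual_state_cost.{s}", (0.0, np.inf)) for s in ("none", "mild", "moderate", "severe", "very_severe")]
    + [(f"values.bsc_cost.{s}", (0.0, np.inf)) for s in ("none", "mild", "moderate", "severe", "very_severe")]
    + [
        ("drug.vial_price", (0.0, np.inf)),
        ("drug.sessions_per_week", (0.0, np.inf)),
        ("econ.discount_rate_annual", (0.0, 0.999)),
        ("econ.ae_cost_per_event", (0.0, np.inf)),
        ("econ.transplant_cost_once", (0.0, np.inf)),
        ("econ.posttransplant_annual_cost", (0.0, np.inf)),
        ("hazards.hr_moderate", (1e-6, np.inf)),
        ("hazards.hr_severe", (1e-6, np.inf)),
        ("hazards.hr_very_severe", (1e-6, np.inf)),
    ]
)


@dataclass
class DSASpec:
    """One-way sensitivity specification."""

    relative_range: float = 0.2  # low/high = base -/+ 20% unless absolute ranges given
    impact_floor: float = 1000.0  # report only swings of at least this (GBP/QALY)
    parameters: list | None = None  # None -> DEFAULT_DSA_PARAMETERS
    absolute_ranges: dict | None = None  # path -> (low, high), overrides relative

    def __post_init__(self) -> None:
        if self.relative_range <= 0:
            raise ConfigurationError(f"relative_range must be > 0, got {self.relative_range}")


def _get_path(cfg: ModelConfig, path: str):
    obj = cfg
    parts = path.split(".")
    for p in parts[:-1]:
        obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
    last = parts[-1]
    return obj[last] if isinstance(obj, dict) else getattr(obj, last)


def _set_path(cfg: ModelConfig, path: str, value) -> None:
    obj = cfg
    parts = path.split(".")
    for p in parts[:-1]:
        obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
    last = parts[-1]
    if isinstance(obj, dict):
        obj[last] = value
    else:
        setattr(obj, last, value)


def run_dsa(base_config: ModelConfig, spec: DSASpec | None = None) -> pd.DataFrame:
    """One-way sensitivity analysis with tornado ranking.

    Returns a DataFrame (one row per varied parameter, largest swing
    first) with the ICER and incremental NMB at the low and high value;
    parameters whose ICER swing is below ``spec.impact_floor`` are
    dropped.  Perturbed values falling outside a parameter's admissible
    domain are clamped with a logged warning.
    """
    spec = spec or DSASpec()
    base = run_base_case(base_config)
    base_icer = base.result.icer
    if isinstance(base_icer, str):
        raise ValueError(f"base-case ICER is {base_icer!r}; tornado ranking needs a finite ICER")
    lam = float(base_config.econ.wtp_thresholds[0])
    base_nmb = base.result.nmb[lam]

    params = spec.parameters if spec.parameters is not None else DEFAULT_DSA_PARAMETERS
    rows = []
    for path, domain in params:
        base_val = float(_get_path(base_config, path))
        if spec.absolute_ranges and path in spec.absolute_ranges:
            low, high = spec.absolute_ranges[path]
        else:
            low = base_val * (1.0 - spec.relative_range)
            high = base_val * (1.0 + spec.relative_range)
        if low >= high:
            raise ConfigurationError(f"DSA range for {path!r} has low >= high")
        out = {"parameter": path, "base_value": base_val}
        for label, val in (("low", low), ("high", high)):
            clamped = min(max(val, domain[0]), domain[1])
            if clamped != val:
                logger.warning("DSA: %s=%s outside domain %s, clamped to %s", path, val, domain, clamped)
            cfg = copy.deepcopy(base_config)
            _set_path(cfg, path, clamped)
            res = run_base_case(cfg).result
            out[f"{label}_value"] = clamped
            out[f"icer_{label}"] = res.icer if not isinstance(res.icer, str) else np.nan
            out[f"nmb_{label}"] = res.nmb[lam]
        swings = [abs(out[f"icer_{s}"] - base_icer) for s in ("low", "high")]
        out["icer_swing"] = np.nanmax(swings) if not all(np.isnan(s) for s in swings) else np.nan
        out["nmb_swing"] = max(abs(out["nmb_low"] - base_nmb), abs(out["nmb_high"] - base_nmb))
        rows.append(out)
    df = pd.DataFrame(rows).sort_values("icer_swing", ascending=False).reset_index(drop=True)
    df = df[df["icer_swing"] >= spec.impact_floor].reset_index(drop=True)
    df.attrs["base_icer"] = base_icer
    df.attrs["base_nmb"] = base_nmb
    return df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSASpec:
    """Probabilistic sensitivity specification.

    All sampling distributions are centred on (have mean equal to) the
    base value.  Coefficients of variation of 0 make a parameter class a
    point mass; ``dirichlet_strength=None`` freezes the transition rows.
    """

    n_iterations: int = 1000
    seed: int = 0
    utility_cv: float = 0.1
    cost_cv: float = 0.1
    hr_cv: float = 0.1
    prob_cv: float = 0.1
    dirichlet_strength: float | None = 1000.0
    responder_sd: float | None = None  # None -> binomial SE at the cohort size

    def __post_init__(self) -> None:
        for name in ("utility_cv", "cost_cv", "hr_cv", "prob_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.dirichlet_strength is not None and self.dirichlet_strength <= 0:
            raise ConfigurationError("dirichlet_strength must be > 0 or None")
        if self.n_iterations < 1:
            raise ConfigurationError(f"n_iterations must be >= 1, got {self.n_iterations}")


def _draw_beta(rng, mean: float, cv: float) -> float:
    """Moment-matched beta draw with the given mean; degenerate at cv=0."""
    if cv == 0 or mean in (0.0, 1.0):
        return mean
    sd = cv * mean
    max_sd2 = mean * (1 - mean)
    sd2 = min(sd * sd, 0.9 * max_sd2)  # keep the beta well defined
    nu = mean * (1 - mean) / sd2 - 1.0
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def _draw_gamma(rng, mean: float, cv: float) -> float:
    if cv == 0 or mean == 0.0:
        return mean
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean / shape))


def _draw_lognormal(rng, mean: float, cv: float) -> float:
    if cv == 0:
        return mean
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0  # preserves the arithmetic mean
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _draw_dirichlet_row(rng, row: np.ndarray, strength: float | None) -> np.ndarray:
    if strength is None:
        return row
    out = np.zeros_like(row)
    pos = row > 0
    if pos.sum() <= 1:
        return row
    out[pos] = rng.dirichlet(row[pos] * strength)
    return out


def _sample_iteration(rng, base: BaseCaseOutput, spec: PSASpec):
    """Sample one parameter set.  Draw order is fixed: utilities, state
    costs, BSC costs, transplant costs, AE cost, hazard ratios, schedule
    death then transplant probabilities, matrix rows (difelikefalin then
    placebo), responder fraction."""
    cfg = copy.deepcopy(base.config)
    for s in list(cfg.values.utility):
        cfg.values.utility[s] = _draw_beta(rng, cfg.values.utility[s], spec.utility_cv)
    for s in list(cfg.values.annual_state_cost):
        cfg.values.annual_state_cost[s] = _draw_gamma(rng, cfg.values.annual_state_cost[s], spec.cost_cv)
    for s in list(cfg.values.bsc_cost):
        cfg.values.bsc_cost[s] = _draw_gamma(rng, cfg.values.bsc_cost[s], spec.cost_cv)
    cfg.econ.transplant_cost_once = _draw_gamma(rng, cfg.econ.transplant_cost_once, spec.cost_cv)
    cfg.econ.posttransplant_annual_cost = _draw_gamma(rng, cfg.econ.posttransplant_annual_cost, spec.cost_cv)
    cfg.econ.ae_cost_per_event = _draw_gamma(rng, cfg.econ.ae_cost_per_event, spec.cost_cv)
    for name in ("hr_moderate", "hr_severe", "hr_very_severe"):
        setattr(cfg.hazards, name, _draw_lognormal(rng, getattr(cfg.hazards, name), spec.hr_cv))

    surv = base.config.survival_inputs()
    tbl = surv.schedule.table.copy()
    tbl["p_death"] = [_draw_beta(rng, p, spec.prob_cv) for p in tbl["p_death"]]
    tbl["p_transplant"] = [_draw_beta(rng, p, spec.prob_cv) for p in tbl["p_transplant"]]
    over = tbl["p_death"] + tbl["p_transplant"]
    bad = over > 1.0
    if bad.any():  # renormalise onto the simplex, preserving the ratio
        tbl.loc[bad, "p_death"] /= over[bad]
        tbl.loc[bad, "p_transplant"] /= over[bad]
    schedule = SurvivalSchedule(tbl)
    surv_inputs = SurvivalInputs(schedule, cfg.hazards, surv.life_table, cfg.demographics)

    matrices = {}
    for arm in ("difelikefalin", "placebo"):
        m = base.matrices[arm].probs
        matrices[arm] = TransitionMatrix(
            np.stack([_draw_dirichlet_row(rng, m[i], spec.dirichlet_strength) for i in range(5)]),
            base.matrices[arm].cycle_length_weeks,
        )

    r = base.responder_fraction
    sd = spec.responder_sd
    if sd is None:
        sd = float(np.sqrt(max(r * (1 - r), 0.0) / base.config.cohort.n_per_arm))
    r = _draw_beta(rng, r, sd / r if r > 0 else 0.0)
    return cfg, surv_inputs, matrices, r


def _evaluate(cfg: ModelConfig, base: BaseCaseOutput, surv_inputs, matrices, responder_fraction):
    waning = WaningParams(base.entry_distribution, cfg.waning_horizon_years)
    traces = run_markov(
        base.entry_distribution, matrices, cfg.schedule, surv_inputs, waning, responder_fraction
    )
    totals = {
        arm: accumulate(
            traces[arm], cfg.values, cfg.drug, cfg.econ, arm,
            base.mean_vials_per_session, cfg.schedule.half_cycle_correction,
        )
        for arm in ("difelikefalin", "bsc")
    }
    return compute_icer(totals["difelikefalin"], totals["bsc"], cfg.econ.wtp_thresholds)


@dataclass
class PSAResult:
    iterations: pd.DataFrame  # per-iteration incrementals and per-arm totals
    ceac: pd.DataFrame  # threshold -> probability cost-effective
    mean_incremental_cost: float
    mean_incremental_qaly: float


def run_psa(base_config: ModelConfig, spec: PSASpec | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis.

    The cohort, entry distribution and mean vial use are held at their
    base-case values; utilities, costs, hazard ratios, schedule
    probabilities, transition rows and the responder fraction are drawn
    each iteration from mean-preserving distributions, and the full model
    is re-evaluated.  Identical seeds give identical iteration tables.
    """
    spec = spec or PSASpec()
    base = run_base_case(base_config)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for it in range(spec.n_iterations):
        cfg, surv_inputs, matrices, r = _sample_iteration(rng, base, spec)
        res = _evaluate(cfg, base, surv_inputs, matrices, r)
        rows.append(
            {
                "iteration": it,
                "cost_dfk": res.arm_a.total_cost,
                "cost_bsc": res.arm_b.total_cost,
                "qaly_dfk": res.arm_a.total_qaly,
                "qaly_bsc": res.arm_b.total_qaly,
                "inc_cost": res.incremental_cost,
                "inc_ly": res.incremental_ly,
                "inc_qaly": res.incremental_qaly,
            }
        )
    iters = pd.DataFrame(rows)
    thresholds = [float(t) for t in base_config.econ.wtp_thresholds]
    ceac = pd.DataFrame(
        {
            "threshold": thresholds,
            "p_cost_effective": [
                float((lam * iters["inc_qaly"] - iters["inc_cost"] > 0).mean()) for lam in thresholds
            ],
        }
    )
    return PSAResult(
        iters, ceac, float(iters["inc_cost"].mean()), float(iters["inc_qaly"].mean())
    )


def ceac_curve(iterations: pd.DataFrame, thresholds) -> pd.DataFrame:
    """CEAC over an arbitrary threshold grid from an iteration table."""
    return pd.DataFrame(
        {
            "threshold": list(thresholds),
            "p_cost_effective": [
                float((lam * iterations["inc_qaly"] - iterations["inc_cost"] > 0).mean())
                for lam in thresholds
            ],
        }
    )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def tornado_plot(dsa: pd.DataFrame, path) -> None:
    """Horizontal tornado of ICER swings, widest bar on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base_icer = dsa.attrs.get("base_icer", np.nan)
    df = dsa.sort_values("icer_swing")
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(df) + 1.5))
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = row["icer_low"], row["icer_high"]
        left, width = min(lo, hi), abs(hi - lo)
        ax.barh(i, width, left=left, color="#4878a8")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(df)), df["parameter"])
    ax.set_xlabel("ICER (GBP/QALY)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ce_plane_plot(iterations: pd.DataFrame, path, wtp: float = 30000.0) -> None:
    """Cost-effectiveness plane scatter with the WTP line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(iterations["inc_qaly"], iterations["inc_cost"], s=6, alpha=0.4)
    q = np.linspace(*ax.get_xlim(), 10)
    ax.plot(q, wtp * q, "k--", lw=1, label=f"WTP {wtp:,.0f} GBP/QALY")
    ax.axhline(0, color="grey", lw=0.7)
    ax.axvline(0, color="grey", lw=0.7)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (GBP)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
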