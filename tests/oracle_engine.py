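"""Independent brute-force oracles used by the test suite.

Everything here is written from the model's documented contract with
explicit per-cycle arithmetic (no calls into the package), so agreement
between the package and these functions is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

BAND_BOUNDS = [(-np.inf, 8.5), (8.5, 11.5), (11.5, 17.5), (17.5, 21.5), (21.5, np.inf)]


def band_masses_by_quadrature(mean: float, sd: float) -> np.ndarray:
    """Normal mass per severity band by adaptive numerical integration."""
    out = []
    for lo, hi in BAND_BOUNDS:
        val, _ = quad(lambda x: norm.pdf(x, mean, sd), lo, hi)
        out.append(val)
    out = np.array(out)
    return out / out.sum()


def oracle_augment(sev_matrix, p_death_annual, p_tx_annual, hrs, cycle_weeks, q_tx_annual):
    """7x7 per-cycle matrix built with explicit scalar arithmetic."""
    A = np.zeros((7, 7))
    f = cycle_weeks / 52.0
    pt = 1.0 - (1.0 - p_tx_annual) ** f
    for i in range(5):
        pd_adj = 1.0 - (1.0 - p_death_annual) ** hrs[i]
        pdc = 1.0 - (1.0 - pd_adj) ** f
        for j in range(5):
            A[i, j] = sev_matrix[i][j] * (1.0 - pdc - pt)
        A[i, 5] = pt
        A[i, 6] = pdc
    qc = 1.0 - (1.0 - q_tx_annual) ** f
    A[5, 5] = 1.0 - qc
    A[5, 6] = qc
    A[6, 6] = 1.0
    return A


def oracle_subcohort_trace(
    entry,
    runin_matrix,
    annual_matrix,
    run_in_cycles,
    run_in_cycle_weeks,
    horizon_years,
    p_death_by_year,
    p_tx_by_year,
    hrs,
    start_age,
    q_of_age,
    waning_baseline=None,
    waning_horizon=10.0,
):
    """Explicit per-cycle matrix-vector evolution of one sub-cohort.

    ``p_death_by_year``/``p_tx_by_year`` map year-on-dialysis (1-based,
    clamped at 10) to annual probabilities; ``q_of_age`` gives annual
    post-transplant mortality at an integer age.  When a waning baseline
    is supplied, the severity shape over survivors at the end of annual
    cycle y is the min(y/horizon, 1) mixture of the no-waning companion's
    shape and the baseline.
    """
    x = np.zeros(7)
    x[:5] = entry
    x_nw = x.copy()
    rows = [x.copy()]
    t = 0.0
    annual_index = 0
    cycles = [("run_in", run_in_cycle_weeks)] * run_in_cycles + [("annual", 52)] * horizon_years
    for phase, weeks in cycles:
        t_end = t + weeks / 52.0
        year = min(max(1, math.ceil(t_end - 1e-9)), 10)
        M = runin_matrix if phase == "run_in" else annual_matrix
        A = oracle_augment(
            M,
            p_death_by_year[year - 1],
            p_tx_by_year[year - 1],
            hrs,
            weeks,
            q_of_age(int(start_age + t)),
        )
        x = x @ A
        x_nw = x_nw @ A
        if phase == "annual":
            annual_index += 1
            if waning_baseline is not None:
                mass, mass_nw = x[:5].sum(), x_nw[:5].sum()
                if mass > 0 and mass_nw > 0:
                    w = min(annual_index / waning_horizon, 1.0)
                    shape = (1.0 - w) * (x_nw[:5] / mass_nw) + w * np.asarray(waning_baseline)
                    x[:5] = shape * mass
        rows.append(x.copy())
        t = t_end
    return np.array(rows)


def oracle_accumulate(occ, times, on_trt, tx_inflow, utilities, annual_costs, drug_cost_year,
                      ae_cost_year, tx_once, rate):
    """Spreadsheet-style discounted accumulation, cycle by cycle.

    ``occ`` has one row per time point (first row = entry); accrual is on
    end-of-cycle occupancy discounted at end-of-cycle time.
    """
    ly = qaly = cost = 0.0
    for k in range(1, len(times)):
        dt = times[k] - times[k - 1]
        df = 1.0 / (1.0 + rate) ** times[k]
        alive = sum(occ[k][:6])
        ly += alive * dt * df
        qaly += sum(occ[k][j] * utilities[j] for j in range(7)) * dt * df
        c = sum(occ[k][j] * annual_costs[j] for j in range(7)) * dt
        c += drug_cost_year * on_trt[k] * dt
        c += ae_cost_year * alive * dt
        cost += c * df + tx_inflow[k] * tx_once * df
    return cost, ly, qaly
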