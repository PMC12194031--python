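"""Discounting, drug costing, accumulation, ICER/NMB."""

import numpy as np
import pandas as pd
import pytest

from ckdap_cea.economics import (
    ICER_DOMINANT,
    ICER_UNDEFINED,
    ArmTotals,
    DrugCostParams,
    EconParams,
    HealthStateValues,
    accumulate,
    annual_drug_cost,
    compute_icer,
    discount_factor,
    results_table,
    vials_per_session,
)
from ckdap_cea.severity_transitions import STATES


class TestDiscounting:
    def test_time_zero_factor_is_one(self):
        assert discount_factor(0.0, 0.035) == 1.0

    def test_one_year_at_base_rate(self):
        assert discount_factor(1.0, 0.035) == pytest.approx(1.0 / 1.035)

    def test_zero_rate_never_discounts(self):
        assert discount_factor(17.3, 0.0) == 1.0


class TestDrugCost:
    params = DrugCostParams()

    @pytest.mark.parametrize("weight,expected", [(80.0, 1), (140.0, 2), (0.1, 1), (130.0, 1), (130.1, 2)])
    def test_vial_rounding(self, weight, expected):
        # ceil(weight * 0.5 / 65), minimum one vial
        assert vials_per_session(weight, self.params) == expected

    def test_annual_cost_product(self):
        # 31.90 * 1 * 2.96 * 52 = 4910.048
        assert annual_drug_cost(self.params, 1.0) == pytest.approx(4910.048)

    def test_zero_price_is_free(self):
        p = DrugCostParams(vial_price=1e-12)
        assert annual_drug_cost(p, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_unrounded_session_frequency_reproduces_published_annual_cost(self):
        """2.96 sessions/week gives 4910.05; the published 4915.02 implies ~2.963."""
        assert annual_drug_cost(self.params, 1.0) == pytest.approx(4915.02, rel=2e-3)
        p = DrugCostParams(sessions_per_week=2.963)
        assert annual_drug_cost(p, 1.0) == pytest.approx(4915.02, abs=0.05)


def _trace(times, occ_rows, on_trt=None, tx_inflow=None):
    n = len(times)
    df = pd.DataFrame(occ_rows, columns=list(STATES))
    df.insert(0, "time_years", times)
    df.insert(0, "cycle", range(n))
    df["tx_inflow"] = tx_inflow if tx_inflow is not None else 0.0
    df["on_treatment"] = on_trt if on_trt is not None else 0.0
    return df


def _none_state_row():
    return [1.0, 0, 0, 0, 0, 0, 0]


class TestAccumulate:
    values = HealthStateValues()
    drug = DrugCostParams()

    def test_two_undiscounted_years_in_none_state(self):
        econ = EconParams(discount_rate_annual=0.0, ae_events_per_patient_year={})
        trace = _trace([0.0, 1.0, 2.0], [_none_state_row()] * 3)
        totals = accumulate(trace, self.values, self.drug, econ, "bsc")
        assert totals.total_qaly == pytest.approx(2 * 0.744)
        assert totals.total_ly == pytest.approx(2.0)
        assert totals.total_cost == pytest.approx(2 * (3726.0 + 31.98))

    def test_unit_utilities_make_qalys_equal_life_years(self):
        values = HealthStateValues()
        values.utility = {s: 1.0 for s in values.utility}
        econ = EconParams()
        trace = _trace([0.0, 1.0, 2.0], [_none_state_row()] * 3)
        totals = accumulate(trace, values, self.drug, econ, "bsc")
        assert totals.total_qaly == pytest.approx(totals.total_ly)

    def test_empty_trace_returns_zeros(self):
        trace = _trace([0.0], [_none_state_row()])
        totals = accumulate(trace, self.values, self.drug, EconParams(), "bsc")
        assert (totals.total_cost, totals.total_ly, totals.total_qaly) == (0.0, 0.0, 0.0)

    def test_discounted_totals_bounded_by_undiscounted(self):
        rng = np.random.default_rng(1)
        occ = rng.dirichlet(np.ones(7), 6)
        trace = _trace(np.arange(6, dtype=float), occ, on_trt=occ[:, :5].sum(1))
        disc = accumulate(trace, self.values, self.drug, EconParams(), "difelikefalin")
        undisc = accumulate(
            trace, self.values, self.drug, EconParams(discount_rate_annual=0.0), "difelikefalin"
        )
        assert disc.total_cost <= undisc.total_cost
        assert disc.total_ly <= undisc.total_ly
        assert disc.total_qaly <= undisc.total_qaly

    def test_cost_accumulation_is_linear_in_unit_costs(self):
        rng = np.random.default_rng(2)
        occ = rng.dirichlet(np.ones(7), 5)
        trace = _trace(np.arange(5, dtype=float), occ, on_trt=occ[:, :5].sum(1), tx_inflow=0.01)
        base = accumulate(trace, self.values, self.drug, EconParams(), "difelikefalin")
        doubled_values = HealthStateValues(
            utility=dict(self.values.utility),
            annual_state_cost={s: 2 * c for s, c in self.values.annual_state_cost.items()},
            bsc_cost={s: 2 * c for s, c in self.values.bsc_cost.items()},
        )
        drug2 = DrugCostParams(vial_price=2 * self.drug.vial_price)
        econ2 = EconParams(
            ae_cost_per_event=2 * 33.19,
            transplant_cost_once=2 * 17000.0,
            posttransplant_annual_cost=2 * 5000.0,
        )
        twice = accumulate(trace, doubled_values, drug2, econ2, "difelikefalin")
        assert twice.total_cost == pytest.approx(2 * base.total_cost, rel=1e-12)
        assert twice.total_qaly == pytest.approx(base.total_qaly)

    def test_agrees_with_spreadsheet_oracle_on_random_traces(self):
        from oracle_engine import oracle_accumulate

        rng = np.random.default_rng(3)
        econ = EconParams()
        for _ in range(20):
            n = int(rng.integers(2, 9))
            occ = rng.dirichlet(np.ones(7), n)
            times = np.cumsum(rng.uniform(0.1, 1.5, n))
            times[0] = 0.0
            on_trt = occ[:, :5].sum(1) * rng.random(n)
            tx_in = rng.uniform(0, 0.02, n)
            trace = _trace(times, occ, on_trt=on_trt, tx_inflow=tx_in)
            got = accumulate(trace, self.values, self.drug, econ, "difelikefalin")
            utilities = [self.values.utility[s] for s in STATES[:5]] + [self.values.utility["transplant"], 0.0]
            annual_costs = [
                self.values.annual_state_cost[s] + self.values.bsc_cost[s] for s in STATES[:5]
            ] + [econ.posttransplant_annual_cost, 0.0]
            cost, ly, qaly = oracle_accumulate(
                occ, times, on_trt, tx_in, utilities, annual_costs,
                annual_drug_cost(self.drug, 1.0),
                econ.ae_events_per_patient_year["difelikefalin"] * econ.ae_cost_per_event,
                econ.transplant_cost_once, econ.discount_rate_annual,
            )
            assert got.total_cost == pytest.approx(cost, abs=1e-10 * max(1, abs(cost)))
            assert got.total_ly == pytest.approx(ly, abs=1e-10)
            assert got.total_qaly == pytest.approx(qaly, abs=1e-10)


class TestICER:
    def test_simple_ratio(self):
        res = compute_icer(ArmTotals(100.0, 1.0, 1.0), ArmTotals(0.0, 0.0, 0.0))
        assert res.icer == pytest.approx(100.0)

    def test_identical_arms_flag_undefined(self):
        a = ArmTotals(500.0, 2.0, 1.5)
        res = compute_icer(a, ArmTotals(400.0, 2.0, 1.5))
        assert res.icer == ICER_UNDEFINED
        assert res.nmb[30000.0] == pytest.approx(-100.0)

    def test_cheaper_and_better_is_dominant(self):
        res = compute_icer(ArmTotals(100.0, 2.0, 2.0), ArmTotals(200.0, 1.0, 1.0))
        assert res.icer == ICER_DOMINANT

    def test_published_incrementals_reproduce_published_ratio(self):
        # incremental cost 7814 GBP over 0.26051 QALYs -> ~29,995 GBP/QALY
        res = compute_icer(ArmTotals(7814.0, 0.11, 0.26051), ArmTotals(0.0, 0.0, 0.0))
        assert res.icer == pytest.approx(29995.0, abs=1.0)

    def test_nmb_definition(self):
        res = compute_icer(
            ArmTotals(1000.0, 0.0, 0.1), ArmTotals(0.0, 0.0, 0.0), wtp_thresholds=(20000.0,)
        )
        assert res.nmb[20000.0] == pytest.approx(20000.0 * 0.1 - 1000.0)


def test_results_table_layout():
    res = compute_icer(ArmTotals(31516.0, 4.64, 3.20), ArmTotals(23702.0, 4.53, 2.93))
    tbl = results_table(res)
    assert list(tbl["quantity"]) == ["total_cost_gbp", "total_life_years", "total_qalys"]
    assert tbl.loc[0, "incremental"] == pytest.approx(7814.0)
    assert tbl.loc[1, "incremental"] == pytest.approx(0.11)
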