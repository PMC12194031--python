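"""Cohort engine: responder split, trace properties, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from ckdap_cea.markov_engine import (
    ModelSchedule,
    ResponderRule,
    SurvivalInputs,
    compute_responder_fraction,
    entry_distribution_from_records,
    run_markov,
)
from ckdap_cea.severity_transitions import STATES, TransitionMatrix, WaningParams
from ckdap_cea.survival_model import CohortDemographics, MortalityHazards
from ckdap_cea.synthetic_cohort import SurvivalSchedule, default_life_table
from oracle_engine import oracle_subcohort_trace


def _surv(p_death, p_tx, hazards=None, demo=None):
    sched = SurvivalSchedule(
        pd.DataFrame({"year": range(1, 11), "p_death": p_death, "p_transplant": p_tx})
    )
    return SurvivalInputs(
        sched,
        hazards or MortalityHazards(1, 1, 1, 1, 1),
        default_life_table(),
        demo or CohortDemographics(59, 0.4),
    )


def _records(baselines, week12s, arm="difelikefalin"):
    return pd.DataFrame({"arm": arm, "score_baseline": baselines, "score_week12": week12s})


class TestResponderFraction:
    def test_all_respond_under_point_rule(self):
        recs = _records([18, 20, 22], [12, 14, 16])
        assert compute_responder_fraction(recs, ResponderRule("point_improvement", 5)) == 1.0

    def test_no_category_change_means_zero(self):
        recs = _records([18, 19, 20], [18, 19, 20])
        assert compute_responder_fraction(recs, ResponderRule("category_improvement", 1)) == 0.0

    def test_category_rule_counts_band_changes(self):
        # 18(severe)->15(moderate) responds; 18->18 does not
        recs = _records([18, 18], [15, 18])
        assert compute_responder_fraction(recs, ResponderRule()) == 0.5

    def test_empty_arm_errors(self):
        with pytest.raises(ValueError):
            compute_responder_fraction(_records([18], [15], arm="placebo"), ResponderRule())


class TestTraces:
    entry = np.array([0.0, 0.0, 0.5, 0.3, 0.2])

    def _matrices(self, m_dfk=None, m_bsc=None):
        ident = TransitionMatrix(np.eye(5))
        return {"difelikefalin": m_dfk or ident, "placebo": m_bsc or ident}

    def test_identity_dynamics_and_no_mortality_give_constant_trace(self):
        traces = run_markov(
            self.entry, self._matrices(), ModelSchedule(horizon_years=5),
            _surv(0.0, 0.0), None, 0.5,
        )
        for tr in traces.values():
            occ = tr[list(STATES)].to_numpy()
            np.testing.assert_allclose(occ, np.tile(occ[0], (len(occ), 1)), atol=1e-14)

    def test_two_state_toy_geometric_decay(self):
        """Single severity state, 20% annual mortality: alive 0.8, 0.64, 0.512."""
        entry = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        sched = ModelSchedule(run_in_cycles=0, horizon_years=3)
        traces = run_markov(entry, self._matrices(), sched, _surv(0.2, 0.0), None, 1.0)
        alive = 1.0 - traces["bsc"]["death"].to_numpy()
        np.testing.assert_allclose(alive, [1.0, 0.8, 0.64, 0.512], atol=1e-12)

    def test_zero_responders_with_equal_matrices_collapses_to_bsc(self):
        rng = np.random.default_rng(5)
        m = TransitionMatrix(rng.dirichlet(np.ones(5), 5))
        waning = WaningParams(self.entry)
        traces = run_markov(
            self.entry, self._matrices(m, m), ModelSchedule(horizon_years=15),
            _surv(0.12, 0.03), waning, 0.0,
        )
        np.testing.assert_allclose(
            traces["difelikefalin"][list(STATES)].to_numpy(),
            traces["bsc"][list(STATES)].to_numpy(),
            atol=1e-14,
        )

    def test_row_conservation_and_death_monotonicity(self):
        rng = np.random.default_rng(8)
        m1 = TransitionMatrix(rng.dirichlet(np.ones(5), 5))
        m2 = TransitionMatrix(rng.dirichlet(np.ones(5), 5))
        traces = run_markov(
            self.entry, self._matrices(m1, m2), ModelSchedule(horizon_years=30),
            _surv(0.15, 0.03, MortalityHazards()), WaningParams(self.entry), 0.6,
        )
        for tr in traces.values():
            occ = tr[list(STATES)].to_numpy()
            np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-10)
            assert (np.diff(tr["death"].to_numpy()) >= -1e-12).all()

    def test_entry_distribution_restricted_to_moderate_or_worse(self):
        bad = np.array([0.2, 0.0, 0.5, 0.3, 0.0])
        with pytest.raises(ValueError):
            run_markov(bad, self._matrices(), ModelSchedule(), _surv(0.1, 0.02), None, 0.5)


def test_engine_matches_brute_force_oracle_on_random_configurations():
    """Full-arm traces equal explicit per-cycle matrix-vector products."""
    rng = np.random.default_rng(2024)
    lt = default_life_table()
    demo = CohortDemographics(59, 0.4)
    for _ in range(25):
        m_dfk = rng.dirichlet(np.ones(5) * rng.uniform(0.5, 3), 5)
        m_bsc = rng.dirichlet(np.ones(5) * rng.uniform(0.5, 3), 5)
        p_death = rng.uniform(0.02, 0.3, 10)
        p_tx = rng.uniform(0.0, 0.08, 10)
        hrs = rng.uniform(0.8, 1.6, 5)
        entry3 = rng.dirichlet(np.ones(3))
        entry = np.array([0.0, 0.0, *entry3])
        horizon = int(rng.integers(3, 12))
        r = float(rng.uniform(0, 1))
        surv = SurvivalInputs(
            SurvivalSchedule(pd.DataFrame({"year": range(1, 11), "p_death": p_death, "p_transplant": p_tx})),
            MortalityHazards(*hrs),
            lt,
            demo,
        )
        waning = WaningParams(entry)
        traces = run_markov(
            entry,
            {"difelikefalin": TransitionMatrix(m_dfk), "placebo": TransitionMatrix(m_bsc)},
            ModelSchedule(horizon_years=horizon),
            surv,
            waning,
            r,
        )

        def q_of_age(age):
            return lt.q_mixed(age, demo.female_fraction)

        kw = dict(
            run_in_cycles=3, run_in_cycle_weeks=4, horizon_years=horizon,
            p_death_by_year=p_death, p_tx_by_year=p_tx, hrs=hrs,
            start_age=59, q_of_age=q_of_age,
        )
        bsc = oracle_subcohort_trace(entry, m_bsc, m_bsc, waning_baseline=entry, **kw)
        resp = oracle_subcohort_trace(entry, m_dfk, m_dfk, **kw)
        nonresp = oracle_subcohort_trace(entry, m_dfk, m_bsc, waning_baseline=entry, **kw)
        np.testing.assert_allclose(traces["bsc"][list(STATES)].to_numpy(), bsc, atol=1e-12)
        np.testing.assert_allclose(
            traces["difelikefalin"][list(STATES)].to_numpy(),
            r * resp + (1 - r) * nonresp,
            atol=1e-12,
        )


def test_entry_distribution_from_records_counts_bands():
    recs = pd.DataFrame({"score_baseline": [14, 15, 19, 23], "arm": "placebo"})
    np.testing.assert_allclose(
        entry_distribution_from_records(recs), [0, 0, 0.5, 0.25, 0.25]
    )
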