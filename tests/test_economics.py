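import dataclasses

import numpy as np
import pytest

import housefirst as hf
from housefirst.dynamics import EventSummary, state_vectors
from housefirst.economics import CostBreakdown, OutcomeSet

from conftest import make_draw, single_stratum_cohort, zero_draw


def _outcome(qalys, total_cost):
    cb = CostBreakdown(components={"background": total_cost, "housing": 0.0,
                                   "excess_oud": 0.0, "excess_homeless": 0.0,
                                   "treatment": 0.0, "naloxone": 0.0,
                                   "per_overdose": 0.0})
    ev = EventSummary(5.0, 0, 0, 0, 0, 0, 0)
    return OutcomeSet(qalys=qalys, life_years=qalys, costs=cb, events=ev)


class TestCosts:
    def test_component_arithmetic_unhoused_out_of_treatment(self, ps):
        # mass pinned in O2_U for one undiscounted year, male aged 30:
        # background 2764 + excess disorder 8827 + excess homelessness 13823
        # + overdose events at 0.1368/yr x (3029 care + 87 naloxone refill)
        # + one 87 naloxone provision at entry
        draw = zero_draw(ps, od_out_u=0.1368, surv_u=1.0, c_oud_out=8827.0,
                         c_homeless=13823.0, c_od_u=3029.0, c_naloxone=87.0,
                         bg_cost_male_30=2764.0)
        c = single_stratum_cohort(age=30)
        traj = hf.integrate_cohort(c, draw, "status_quo", horizon=1.0)
        cb = hf.accrue_costs(traj, draw, discount_rate=0.0, window=1.0)
        assert cb.components["background"] == pytest.approx(2764.0, rel=1e-9)
        assert cb.components["excess_oud"] == pytest.approx(8827.0, rel=1e-9)
        assert cb.components["excess_homeless"] == pytest.approx(13823.0,
                                                                 rel=1e-9)
        assert cb.components["per_overdose"] == pytest.approx(
            0.1368 * 3029.0, rel=1e-9)
        assert cb.components["naloxone"] == pytest.approx(
            87.0 + 0.1368 * 87.0, rel=1e-9)
        assert cb.health_care == pytest.approx(
            2764 + 8827 + 13823 + 0.1368 * (3029 + 87) + 87, rel=1e-9)
        assert cb.housing == 0.0

    def test_discounting_reduces_totals(self, traj_pair, bdraw):
        traj = traj_pair["status_quo"]
        undisc = hf.accrue_costs(traj, bdraw, discount_rate=0.0)
        disc = hf.accrue_costs(traj, bdraw, discount_rate=0.03)
        assert disc.total < undisc.total

    def test_ledger_additivity(self, traj_pair, bdraw):
        for traj in traj_pair.values():
            cb = hf.accrue_costs(traj, bdraw)
            assert cb.total == pytest.approx(
                sum(cb.components.values()), rel=1e-9)
            assert cb.total == pytest.approx(cb.health_care + cb.housing,
                                             rel=1e-9)
            assert all(v >= 0 for v in cb.components.values())

    def test_doubling_housing_cost_scales_only_housing_ledger(
            self, ps, traj_pair):
        traj = traj_pair["housing"]
        base = hf.base_draw(ps)
        doubled = make_draw(ps, housing_cost=2 * base.housing_cost)
        a = hf.accrue_costs(traj, base)
        b = hf.accrue_costs(traj, doubled)
        assert b.housing == pytest.approx(2 * a.housing, rel=1e-12)
        assert b.health_care == pytest.approx(a.health_care, rel=1e-12)


class TestQALYs:
    def test_closed_form_with_unit_utilities(self, ps):
        # no mortality, every multiplier 1: integral of e^(-rho t) over [0,T]
        draw = zero_draw(ps, **{f: 1.0 for f in
                                ("q_out_h", "q_out_u", "q_treat_h",
                                 "q_treat_u", "q_abst1_h", "q_abst1_u",
                                 "q_abst10_h", "q_abst10_u")})
        c = single_stratum_cohort(age=30)
        horizon = 40.0
        traj = hf.integrate_cohort(c, draw, "status_quo", horizon=horizon)
        rho = 0.03
        got = hf.accrue_qalys(traj, draw, discount_rate=rho)
        assert got == pytest.approx((1 - np.exp(-rho * horizon)) / rho,
                                    rel=1e-4)

    def test_zero_utilities_give_zero(self, ps, traj_pair):
        draw = zero_draw(ps)
        assert hf.accrue_qalys(traj_pair["status_quo"], draw) == 0.0

    def test_housed_utilities_dominate_unhoused(self, bdraw):
        vec = state_vectors(bdraw)
        assert np.all(vec.qol[:14] > vec.qol[14:28])

    def test_qalys_bounded_by_undiscounted_life_years(self, traj_pair, bdraw):
        for traj in traj_pair.values():
            q = hf.accrue_qalys(traj, bdraw)
            ly = hf.economics.life_years(traj)
            assert 0.0 <= q <= ly

    def test_invalid_multiplier_rejected(self, ps, traj_pair):
        bad = make_draw(ps, q_out_h=1.5)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            hf.accrue_qalys(traj_pair["housing"], bad)


class TestICER:
    def test_published_incremental_arithmetic(self):
        # incremental cost 96k over 3.59 QALYs gained: 26 741 per QALY,
        # the published rounded value is 26 800
        r = hf.compare_arms(_outcome(3.71, 449000.0),
                            _outcome(3.71 + 3.59, 449000.0 + 96000.0))
        assert r.icer == pytest.approx(96000.0 / 3.59, rel=1e-12)
        assert r.icer == pytest.approx(26800.0, rel=0.01)
        assert r.flag == ""

    def test_identical_arms_undefined(self):
        r = hf.compare_arms(_outcome(3.0, 100.0), _outcome(3.0, 100.0))
        assert r.icer is None and r.flag == "undefined"

    def test_dominance_flags(self):
        assert hf.compare_arms(_outcome(3.0, 100.0),
                               _outcome(4.0, 90.0)).flag == "dominant"
        assert hf.compare_arms(_outcome(4.0, 90.0),
                               _outcome(3.0, 100.0)).flag == "dominated"


class TestFastPathConsistency:
    def test_kernel_outcomes_match_trajectory_accounting(
            self, ps, cohort, bdraw, traj_pair):
        """The PSA fast path and the trajectory-based accounting are two
        routes to the same integrals and must agree."""
        row = hf.evaluate_draw(cohort, bdraw)
        for arm, p in (("status_quo", "sq"), ("housing", "hi")):
            oc = hf.outcome_set(traj_pair[arm], bdraw)
            assert row[f"{p}_qalys"] == pytest.approx(oc.qalys, rel=1e-9)
            assert row[f"{p}_cost_hc"] == pytest.approx(
                oc.costs.health_care, rel=1e-9)
            assert row[f"{p}_cost_housing"] == pytest.approx(
                oc.costs.housing, abs=1e-6)
            assert row[f"{p}_deaths"] == pytest.approx(
                oc.events.deaths_total, rel=1e-9)
            assert row[f"{p}_od_total"] == pytest.approx(
                oc.events.overdoses_total, rel=1e-9)
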