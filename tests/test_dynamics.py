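import numpy as np
import pytest
from scipy.linalg import expm

import housefirst as hf
from housefirst.dynamics import (D_OD, D_OTHER, N_STATES, build_edges,
                                 state_index)

from conftest import make_draw, single_stratum_cohort, zero_draw


class TestRateAssembly:
    def test_fatal_overdose_rate_unhoused_out_of_treatment(self, bdraw):
        ra = hf.assemble_rates(bdraw)
        # 0.1368/yr incidence, survival 0.883 per event
        assert ra.rate("O2_U", "D_OD") == pytest.approx(0.1368 * (1 - 0.883),
                                                        rel=1e-9)

    def test_treatment_success_rates(self, bdraw):
        ra = hf.assemble_rates(bdraw)
        assert ra.rate("T_H", "A1_H") == pytest.approx(0.316)
        assert ra.rate("T_U", "A1_U") == pytest.approx(0.029)

    def test_housing_loss_applies_to_every_housed_state(self, bdraw):
        ra = hf.assemble_rates(bdraw)
        for base in ("O1", "O2", "I", "T", "A1", "A2_5", "A2_9"):
            assert ra.rate(f"{base}_H", f"{base}_U") == pytest.approx(0.0820)
            # housing is never regained
            assert ra.rate(f"{base}_U", f"{base}_H") == 0.0

    def test_background_mortality_enters_at_stratum_age(self, bdraw, cohort):
        s = next(x for x in cohort.strata if x.sex == "male"
                 and x.age_at_entry == 46)
        lt = cohort.life_tables["male"]
        ra = hf.assemble_rates(bdraw, s, t=0.0, life_table=lt)
        mu = hf.background_mortality(lt, 46)
        assert ra.mortality_background[state_index("O2_H")] == mu
        # induction carries the all-cause multiplier (methadone)
        assert ra.mortality_background[state_index("I_H")] == \
            pytest.approx(14.0 * mu)

    def test_unknown_state_rejected(self, bdraw):
        with pytest.raises(KeyError, match="unknown state"):
            hf.assemble_rates(bdraw).rate("O3_H", "D_OD")

    def test_witnessing_decomposition_neutral_at_reference(self, bdraw):
        from housefirst.dynamics import effective_survival
        assert effective_survival(bdraw, "H") == pytest.approx(0.880)
        low = make_draw(hf.load_parameter_set(), witness_h=0.12)
        assert effective_survival(low, "H") < 0.880


class TestIntegration:
    def test_null_dynamics_constant_occupancy(self, ps):
        c = single_stratum_cohort()
        traj = hf.integrate_cohort(c, zero_draw(ps), "status_quo",
                                   horizon=10.0)
        i = state_index("O2_U")
        assert np.allclose(traj.occ[:, i, :], 1.0, atol=1e-12)
        ev = hf.summarize_events(traj, 5.0)
        assert ev.overdoses_total == 0.0 and ev.deaths_total == 0.0

    def test_three_state_toy_matches_matrix_exponential(self, ps):
        # one live state (O2_U) flowing only to the two death sinks
        draw = zero_draw(ps, od_out_u=0.2, surv_u=0.7, ex_oud_out_u=0.05,
                         ex_homeless_out_u=0.02)
        c = single_stratum_cohort()
        traj = hf.integrate_cohort(c, draw, "status_quo", horizon=4.0)
        f = 0.2 * 0.3          # fatal overdose rate
        m = 0.05 + 0.02        # excess mortality
        q = np.array([[-(f + m), f, m], [0, 0, 0], [0, 0, 0]])
        for t in (1.0, 2.5, 4.0):
            it = int(round(t / traj.step))
            p = expm(q.T * t) @ np.array([1.0, 0.0, 0.0])
            got = traj.occ[0, [state_index("O2_U"), D_OD, D_OTHER], it]
            assert np.allclose(got, p, atol=1e-6)

    def test_pure_background_survival_matches_life_table(self, ps):
        # with every other rate zeroed, survival is the life-table product
        c = single_stratum_cohort(age=46, zero_mortality=False)
        lt = c.life_tables["male"]
        traj = hf.integrate_cohort(c, zero_draw(ps), "status_quo",
                                   horizon=10.0)
        for t in (1, 3, 5, 10):
            expected = np.exp(-sum(hf.background_mortality(lt, 46 + y)
                                   for y in range(t)))
            it = int(round(t / traj.step))
            alive = 1.0 - traj.occ[0, D_OTHER, it]
            assert alive == pytest.approx(expected, abs=1e-3)

    def test_mass_conservation(self, traj_pair):
        for traj in traj_pair.values():
            assert traj.mass_error() <= 1e-6

    def test_initial_condition_contract(self, traj_pair):
        sq, hi = traj_pair["status_quo"], traj_pair["housing"]
        unhoused = [state_index(f"O2_U")]
        assert np.allclose(sq.occ[:, state_index("O2_U"), 0], 1.0)
        assert np.allclose(hi.occ[:, state_index("O2_H"), 0], 1.0)
        # housed mass stays strictly positive at finite times
        housed_mass = hi.occ[:, :14, :].sum(axis=1)
        assert housed_mass.min() > 0.0

    def test_event_accounting_identities(self, traj_pair):
        for traj in traj_pair.values():
            ev = hf.summarize_events(traj, 5.0)
            assert ev.overdoses_total == pytest.approx(
                ev.overdoses_fatal + ev.overdoses_nonfatal, rel=1e-12)
            assert ev.deaths_total == pytest.approx(
                ev.deaths_od + ev.deaths_other, rel=1e-12)
            ev0 = hf.summarize_events(traj, 0.0)
            assert ev0.overdoses_total == 0.0 and ev0.deaths_total == 0.0

    def test_counters_nondecreasing(self, traj_pair):
        traj = traj_pair["status_quo"]
        assert np.all(np.diff(traj.od_total_cum, axis=1) >= -1e-12)
        assert np.all(np.diff(traj.occ[:, D_OD, :], axis=1) >= -1e-9)

    def test_step_halving_changes_outcomes_below_half_percent(
            self, cohort, bdraw):
        for arm in ("status_quo", "housing"):
            a = hf.integrate_cohort(cohort, bdraw, arm, step=1 / 12)
            b = hf.integrate_cohort(cohort, bdraw, arm, step=1 / 24)
            for traj_a, traj_b in ((a, b),):
                ev_a = hf.summarize_events(traj_a, 5.0)
                ev_b = hf.summarize_events(traj_b, 5.0)
                assert ev_a.deaths_total == pytest.approx(
                    ev_b.deaths_total, rel=5e-3)
                assert ev_a.overdoses_total == pytest.approx(
                    ev_b.overdoses_total, rel=5e-3)
                qa = hf.accrue_qalys(traj_a, bdraw)
                qb = hf.accrue_qalys(traj_b, bdraw)
                assert qa == pytest.approx(qb, rel=5e-3)
                ca = hf.accrue_costs(traj_a, bdraw)
                cb = hf.accrue_costs(traj_b, bdraw)
                assert ca.total == pytest.approx(cb.total, rel=5e-3)

    def test_higher_mortality_weakly_decreases_survivors(self, ps, cohort,
                                                         bdraw):
        worse = make_draw(ps, ex_homeless_out_u=2 * bdraw.ex_homeless_out_u)
        base = hf.summarize_events(
            hf.integrate_cohort(cohort, bdraw, "status_quo"), 5.0)
        high = hf.summarize_events(
            hf.integrate_cohort(cohort, worse, "status_quo"), 5.0)
        assert high.deaths_total >= base.deaths_total

    def test_extreme_housing_loss_recovers_status_quo(self, ps):
        c = single_stratum_cohort(age=45, zero_mortality=False)
        fast = make_draw(ps, loss_rate=500.0)
        step = hf.stable_step(fast)
        hi = hf.integrate_cohort(c, fast, "housing", step=step, horizon=5.0)
        sq = hf.integrate_cohort(c, fast, "status_quo", step=step,
                                 horizon=5.0)
        ev_hi, ev_sq = (hf.summarize_events(t, 5.0) for t in (hi, sq))
        assert ev_hi.deaths_total == pytest.approx(ev_sq.deaths_total,
                                                   rel=0.01)
        assert ev_hi.overdoses_total == pytest.approx(
            ev_sq.overdoses_total, rel=0.01)

    def test_oversized_step_rejected(self, cohort, bdraw):
        with pytest.raises(ValueError, match="at most one month"):
            hf.integrate_cohort(cohort, bdraw, "housing", step=0.5)

    def test_stable_step_subdivides_fast_draws(self, ps, bdraw):
        assert hf.stable_step(bdraw) == pytest.approx(1 / 12)
        fast = make_draw(ps, loss_rate=500.0)
        s = hf.stable_step(fast)
        assert s <= 2.5 / 500.0
        assert (1 / 12) / s == pytest.approx(round((1 / 12) / s))
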