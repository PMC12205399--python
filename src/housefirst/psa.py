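"""Probabilistic sensitivity analysis and named scenario runs.

Each PSA draw samples one parameter realization and evaluates both arms —
status quo (cohort stays unhoused) and housing intervention (cohort housed at
entry) — under the same draw (common random numbers), so incremental results
difference out parameter noise.  Summaries report means and percentile 95%
intervals of the per-draw outcomes; the incremental cost-effectiveness ratio
(ICER) is summarized both as the mean of per-draw ratios and as the ratio of
means.

Named scenarios reproduce the sensitivity analyses: they are pure parameter
transforms applied to the base :class:`~housefirst.params.ParameterSet`
before sampling.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .cohort import MAX_AGE, Cohort
from .dynamics import (LIVE_MASK, build_edges, integrate_cohort, stable_step,
                       state_index, state_vectors)
from .economics import compare_arms, outcome_set
from .params import (ParamValue, ParameterDraw, ParameterSet, base_draw,
                     sample_draw)

__all__ = [
    "Scenario", "SCENARIOS", "apply_scenario", "PSAResults", "run_psa",
    "evaluate_draw", "run_base_case", "run_two_way_grid",
]

ARMS = ("status_quo", "housing")
_PREFIX = {"status_quo": "sq", "housing": "hi"}


# ---------------------------------------------------------------------------
# scenarios

@dataclasses.dataclass(frozen=True)
class Scenario:
    """A named set of parameter overrides.

    Each override is ``(field, op, value)`` with op ``set`` (rescale the
    range so the base equals ``value``), ``scale`` (multiply the range by
    ``value``), or ``copy`` (replace with the ParamValue of field ``value``,
    e.g. copy unhoused rates over housed ones).  Scalar fields accept ``set``
    only.  Overrides apply in order.
    """

    name: str
    description: str = ""
    overrides: tuple[tuple[str, str, object], ...] = ()


def _scale_pv(pv: ParamValue, c: float) -> ParamValue:
    if c == 0.0 or pv.base == 0.0:
        return ParamValue(base=0.0, family="fixed")
    return ParamValue(base=pv.base * c, low=pv.low * c, high=pv.high * c,
                      family=pv.family)


def apply_scenario(ps: ParameterSet, scenario: Scenario) -> ParameterSet:
    """Return a new ParameterSet with the scenario's overrides applied."""
    updates: dict[str, object] = {}

    def current(field: str):
        return updates.get(field, getattr(ps, field))

    for field, op, value in scenario.overrides:
        if not hasattr(ps, field):
            valid = ", ".join(sorted(ParameterSet.model_fields))
            raise KeyError(f"unknown parameter path {field!r}; valid paths: "
                           f"{valid}")
        cur = current(field)
        if isinstance(cur, ParamValue):
            if op == "scale":
                updates[field] = _scale_pv(cur, float(value))
            elif op == "set":
                v = float(value)
                updates[field] = (_scale_pv(cur, v / cur.base)
                                  if cur.base != 0 and v != 0
                                  else ParamValue(base=v, family="fixed"))
            elif op == "copy":
                updates[field] = current(str(value))
            else:
                raise ValueError(f"unknown override op {op!r}")
        else:
            if op != "set":
                raise ValueError(f"scalar field {field!r} supports 'set' only")
            updates[field] = float(value)
    return ps.model_copy(update=updates) if updates else ps


def _qol_u_overrides(mult: float) -> tuple[tuple[str, str, object], ...]:
    out: list[tuple[str, str, object]] = []
    for tag in ("q_out", "q_treat", "q_abst1", "q_abst10"):
        out += [(f"{tag}_u", "copy", f"{tag}_h"), (f"{tag}_u", "scale", mult)]
    return tuple(out)


SCENARIOS: dict[str, Scenario] = {s.name: s for s in (
    Scenario("base", "base-case housing intervention"),
    Scenario(
        "lower_treatment_benefit",
        "housed treatment entry and abstinence 20% lower, discontinuation "
        "and relapse 20% higher",
        (("entry_h", "scale", 0.8), ("succ_h", "scale", 0.8),
         ("abst_h", "scale", 0.8), ("disc_h", "scale", 1.2),
         ("rel1_h", "scale", 1.2), ("rel2_h", "scale", 1.2)),
    ),
    Scenario(
        "no_treatment_effect",
        "housed treatment entry and outcomes equal to unhoused (the full "
        "cascade plus overdose incidence and survival); housing retains its "
        "quality-of-life and mortality benefits only",
        (("entry_h", "copy", "entry_u"), ("disc_h", "copy", "disc_u"),
         ("succ_h", "copy", "succ_u"), ("abst_h", "copy", "abst_u"),
         ("rel1_h", "copy", "rel1_u"), ("rel2_h", "copy", "rel2_u"),
         ("od_out_h", "copy", "od_out_u"), ("od_in_h", "copy", "od_in_u"),
         ("surv_h", "copy", "surv_u")),
    ),
    Scenario(
        "lower_witnessed_overdose",
        "probability of a housed overdose being witnessed 80% lower",
        (("witness_h", "scale", 0.2),),
    ),
    Scenario(
        "doubled_loss_rate",
        "rate of becoming unhoused twice as high",
        (("loss_rate", "scale", 2.0),),
    ),
    Scenario(
        "loss_rate_by_state",
        "becoming unhoused 50% higher out of treatment, 25% higher in "
        "treatment, unchanged for abstinent",
        (("loss_mult_out", "set", 1.5), ("loss_mult_in", "set", 1.25),
         ("loss_mult_abst", "set", 1.0)),
    ),
    Scenario(
        "homeless_mortality_for_housed",
        "excess mortality due to homelessness applies equally when housed",
        (("ex_homeless_out_h", "copy", "ex_homeless_out_u"),
         ("ex_homeless_in_h", "copy", "ex_homeless_in_u")),
    ),
    Scenario(
        "doubled_housing_cost",
        "annual housing cost twice as high",
        (("housing_cost", "scale", 2.0),),
    ),
    Scenario(
        "higher_unhoused_qol",
        "utility multiplier for being unhoused raised to 0.60",
        _qol_u_overrides(0.60),
    ),
)}


# ---------------------------------------------------------------------------
# fast per-draw evaluation

def _tables(cohort: Cohort, ps_or_draw) -> tuple[np.ndarray, np.ndarray]:
    """Background mortality and background-cost tables per (stratum, year)."""
    min_age = min(s.age_at_entry for s in cohort.strata)
    n_years = MAX_AGE - min_age
    mu_tab = cohort.mortality_table(n_years)
    bgc_tab = np.zeros((cohort.n_strata, n_years))
    for i, s in enumerate(cohort.strata):
        mult = 1.0 if s.sex == "male" else ps_or_draw.bg_cost_female_mult
        ages = s.age_at_entry + np.arange(n_years)
        bgc_tab[i] = (ps_or_draw.bg_cost_male_30
                      * (1.0 + ps_or_draw.bg_cost_growth) ** (ages - 30.0)
                      * mult)
    return mu_tab, bgc_tab


def evaluate_draw(cohort: Cohort, draw: ParameterDraw,
                  window: float = 5.0,
                  tables: tuple[np.ndarray, np.ndarray] | None = None,
                  ) -> dict[str, float]:
    """Evaluate both arms for one draw without storing trajectories.

    Returns a flat row of per-arm outcomes (per-person discounted QALYs and
    costs; events per 1000 over the window) plus incremental results.
    """
    mu_tab, bgc_tab = _tables(cohort, draw) if tables is None else tables
    ef, et, er, bg_mult = build_edges(draw)
    vec = state_vectors(draw)
    v_hc = (vec.cost_oud + vec.cost_homeless + vec.cost_treatment
            + vec.cost_od_event)
    weights = np.array([s.weight for s in cohort.strata])
    base_step = stable_step(draw)

    row: dict[str, float] = {"draw_id": draw.draw_id, "step": base_step}
    out = np.empty(7)
    for arm in ARMS:
        x0 = state_index("O2_U" if arm == "status_quo" else "O2_H")
        step = base_step
        for attempt in range(5):  # positivity fallback, deterministic
            n_steps = np.array(
                [max(0, round((MAX_AGE - s.age_at_entry) / step))
                 for s in cohort.strata], dtype=np.int64)
            flag = _kernel.integrate_outcomes(
                x0, ef, et, er, bg_mult, mu_tab, bgc_tab, weights, n_steps,
                step, draw.discount_rate, vec.qol, v_hc, vec.cost_housing,
                vec.od_rate, LIVE_MASK, int(round(window / step)), out)
            if flag == 0:
                break
            step /= 2.0
        else:
            raise RuntimeError(
                f"negative occupancy in draw {draw.draw_id} ({arm}); "
                "step refinement failed")
        p = _PREFIX[arm]
        qalys, hc, housing, od_total, d_od, d_other, ly = out
        hc += draw.c_naloxone  # initial naloxone provision at entry
        row.update({
            f"{p}_qalys": qalys, f"{p}_life_years": ly,
            f"{p}_cost_hc": hc, f"{p}_cost_housing": housing,
            f"{p}_cost_total": hc + housing,
            f"{p}_od_total": od_total * 1000.0,
            f"{p}_od_fatal": d_od * 1000.0,
            f"{p}_od_nonfatal": (od_total - d_od) * 1000.0,
            f"{p}_deaths": (d_od + d_other) * 1000.0,
            f"{p}_deaths_od": d_od * 1000.0,
            f"{p}_deaths_other": d_other * 1000.0,
        })
    row["d_cost"] = row["hi_cost_total"] - row["sq_cost_total"]
    row["d_qaly"] = row["hi_qalys"] - row["sq_qalys"]
    row["icer"] = (row["d_cost"] / row["d_qaly"]
                   if row["d_qaly"] != 0 else np.nan)
    return row


# ---------------------------------------------------------------------------
# PSA driver

_SUMMARY_COLS = [
    "sq_od_fatal", "sq_od_nonfatal", "sq_od_total", "sq_deaths",
    "sq_deaths_other", "sq_qalys", "sq_cost_hc", "sq_cost_housing",
    "sq_cost_total",
    "hi_od_fatal", "hi_od_nonfatal", "hi_od_total", "hi_deaths",
    "hi_deaths_other", "hi_qalys", "hi_cost_hc", "hi_cost_housing",
    "hi_cost_total",
    "d_cost", "d_qaly", "icer",
]


@dataclasses.dataclass(frozen=True)
class PSAResults:
    """Per-draw outcomes for both arms under common random numbers."""

    scenario: str
    seed: int
    n_draws: int
    draws: pd.DataFrame  # one row per draw

    def summary(self) -> pd.DataFrame:
        """Mean and 2.5/97.5 percentiles for every outcome column."""
        rows = []
        for col in _SUMMARY_COLS:
            x = self.draws[col].to_numpy()
            rows.append({"outcome": col, "mean": float(np.mean(x)),
                         "lo": float(np.percentile(x, 2.5)),
                         "hi": float(np.percentile(x, 97.5))})
        return pd.DataFrame(rows).set_index("outcome")

    def mean(self, col: str) -> float:
        return float(self.draws[col].mean())

    @property
    def icer_mean(self) -> float:
        return self.mean("icer")

    @property
    def icer_of_means(self) -> float:
        return self.mean("d_cost") / self.mean("d_qaly")


def run_psa(ps: ParameterSet, cohort: Cohort, n_draws: int, seed: int,
            scenario: Scenario | str | None = None,
            window: float = 5.0, progress: bool = False) -> PSAResults:
    """Run the PSA: ``n_draws`` common-random-number draws, both arms each.

    Fully reproducible from ``(seed, n_draws, configuration, scenario)``;
    draws are independent, so results do not depend on execution order.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    name = scenario.name if scenario is not None else "base"
    if scenario is not None:
        ps = apply_scenario(ps, scenario)
    tables = _tables(cohort, ps)
    rows = []
    for i in range(n_draws):
        draw = sample_draw(ps, seed, i)
        try:
            rows.append(evaluate_draw(cohort, draw, window, tables))
        except Exception as exc:  # annotate with draw context
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        if progress and (i + 1) % 1000 == 0:
            print(f"  PSA {name}: {i + 1}/{n_draws} draws")
    return PSAResults(scenario=name, seed=seed, n_draws=n_draws,
                      draws=pd.DataFrame(rows))


def run_base_case(ps: ParameterSet, cohort: Cohort,
                  scenario: Scenario | str | None = None,
                  step: float = 1.0 / 12.0, window: float = 5.0):
    """Deterministic run at base parameter values via full trajectories.

    Returns ``(outcome_sets, icer_result)`` where ``outcome_sets`` maps arm
    name to its :class:`~housefirst.economics.OutcomeSet` with the complete
    cost ledger.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if scenario is not None:
        ps = apply_scenario(ps, scenario)
    draw = base_draw(ps)
    step = min(step, stable_step(draw, step))
    outcomes = {}
    for arm in ARMS:
        traj = integrate_cohort(cohort, draw, arm, step=step)
        outcomes[arm] = outcome_set(traj, draw, window)
    return outcomes, compare_arms(outcomes["status_quo"], outcomes["housing"])


def run_two_way_grid(ps: ParameterSet, cohort: Cohort,
                     housing_cost_levels: Sequence[float],
                     excess_unhoused_cost_levels: Sequence[float],
                     n_draws: int, seed: int,
                     scenario: Scenario | str | None = None) -> pd.DataFrame:
    """Two-way sensitivity grid: housing cost x excess unhoused care cost.

    One PSA per cell with the common seed; returns a long-format frame with
    mean ICER (of per-draw ratios) and the ratio of means per cell.
    """
    if not len(housing_cost_levels) or not len(excess_unhoused_cost_levels):
        raise ValueError("grid levels must be non-empty")
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if scenario is not None:
        ps = apply_scenario(ps, scenario)
    rows = []
    for hc in housing_cost_levels:
        for ex in excess_unhoused_cost_levels:
            cell = Scenario(
                name=f"grid_h{hc:g}_e{ex:g}",
                overrides=(("housing_cost", "set", hc),
                           ("c_homeless", "set", ex)))
            res = run_psa(apply_scenario(ps, cell), cohort, n_draws, seed)
            rows.append({"housing_cost": hc, "excess_unhoused_cost": ex,
                         "icer_mean": res.icer_mean,
                         "icer_of_means": res.icer_of_means,
                         "d_cost": res.mean("d_cost"),
                         "d_qaly": res.mean("d_qaly")})
    return pd.DataFrame(rows)
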