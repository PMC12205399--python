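"""Core compartmental simulator.

State space
-----------
Each housing side (housed ``H``, unhoused ``U``) carries 14 live states:

* ``O1`` — out of treatment, first month (treatment entry does not apply yet;
  relapse and treatment dropout route here),
* ``O2`` — out of treatment for more than one month,
* ``I``  — treatment induction (one month, elevated all-cause mortality on
  methadone),
* ``T``  — receiving treatment,
* ``A1`` — abstinent, first year,
* ``A2_1 .. A2_9`` — abstinent year bins (years 1-2, ..., 9-10 and beyond),
  a chain encoding duration dependence of relapse and quality of life.

Two absorbing sinks complete the space: overdose death and death from other
causes.  Transitions follow the treatment-cascade rates (entry, induction,
discontinuation, success, relapse, abstinence attainment), housing loss moves
every housed live state to its unhoused counterpart (housing is never
regained), and mortality decomposes into background (age/sex life table),
non-overdose excess due to the disorder, excess due to homelessness, and
fatal overdose.  Survived overdoses accrue as events without a state change.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import _kernel
from .cohort import MAX_AGE, Cohort, CohortStratum, LifeTable, background_mortality
from .params import ParameterDraw

__all__ = [
    "STATE_NAMES", "N_STATES", "N_LIVE", "D_OD", "D_OTHER",
    "state_index", "RateAssembly", "StateVectors", "Trajectory",
    "EventSummary", "state_vectors", "build_edges", "assemble_rates",
    "effective_survival", "stable_step", "integrate_cohort",
    "summarize_events",
]

_SIDE_STATES = ["O1", "O2", "I", "T", "A1"] + [f"A2_{k}" for k in range(1, 10)]
STATE_NAMES: tuple[str, ...] = tuple(
    f"{name}_{side}" for side in ("H", "U") for name in _SIDE_STATES
) + ("D_OD", "D_OTHER")

N_STATES = _kernel.N_STATES
D_OD = _kernel.D_OD
D_OTHER = _kernel.D_OTHER
N_LIVE = 28
N_SIDE = 14  # live states per housing side

_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}


def state_index(name: str) -> int:
    try:
        return _INDEX[name]
    except KeyError:
        raise KeyError(f"unknown state {name!r}; valid states: "
                       f"{', '.join(STATE_NAMES)}") from None


def _idx(base: str, side: str) -> int:
    return state_index(f"{base}_{side}")


LIVE_MASK = np.zeros(N_STATES)
LIVE_MASK[:N_LIVE] = 1.0
HOUSED_MASK = np.zeros(N_STATES)
HOUSED_MASK[:N_SIDE] = 1.0
UNHOUSED_MASK = np.zeros(N_STATES)
UNHOUSED_MASK[N_SIDE:N_LIVE] = 1.0


def effective_survival(draw: ParameterDraw, side: str) -> float:
    """Per-overdose survival probability after the witnessing adjustment.

    The sampled survival probability is decomposed as
    ``1 - [w*d_w + (1-w)*d_u]`` with witnessed death risk ``d_w``, unwitnessed
    risk ``d_u = ratio*d_w``, calibrated at the reference witness probability.
    When the draw's witness probability equals the reference, this returns the
    sampled survival unchanged.
    """
    surv = draw.surv_h if side == "H" else draw.surv_u
    w = draw.witness_h if side == "H" else draw.witness_u
    w0 = draw.witness_ref
    ratio = draw.witness_risk_ratio
    d_w = (1.0 - surv) / (w0 + (1.0 - w0) * ratio)
    d_u = ratio * d_w
    return float(np.clip(1.0 - (w * d_w + (1.0 - w) * d_u), 0.0, 1.0))


@dataclasses.dataclass(frozen=True)
class StateVectors:
    """Per-state accounting vectors derived from one parameter draw."""

    qol: np.ndarray            # quality-of-life multiplier
    od_rate: np.ndarray        # overdose incidence, per year
    od_fatal: np.ndarray       # fatal-overdose rate, per year
    excess_mort: np.ndarray    # non-overdose excess mortality, per year
    cost_oud: np.ndarray       # excess health-care cost of the disorder, $/yr
    cost_homeless: np.ndarray  # excess health-care cost of homelessness, $/yr
    cost_treatment: np.ndarray  # treatment cost, $/yr
    cost_od_event: np.ndarray  # overdose event costs (care + naloxone), $/yr
    cost_housing: np.ndarray   # housing cost, $/yr
    live: np.ndarray           # indicator


def state_vectors(draw: ParameterDraw) -> StateVectors:
    qol = np.zeros(N_STATES)
    od_rate = np.zeros(N_STATES)
    od_fatal = np.zeros(N_STATES)
    excess = np.zeros(N_STATES)
    c_oud = np.zeros(N_STATES)
    c_home = np.zeros(N_STATES)
    c_treat = np.zeros(N_STATES)
    c_odev = np.zeros(N_STATES)
    c_house = np.zeros(N_STATES)

    for side in ("H", "U"):
        housed = side == "H"
        q_out = draw.q_out_h if housed else draw.q_out_u
        q_tr = draw.q_treat_h if housed else draw.q_treat_u
        q_a1 = draw.q_abst1_h if housed else draw.q_abst1_u
        q_a10 = draw.q_abst10_h if housed else draw.q_abst10_u
        od_out = draw.od_out_h if housed else draw.od_out_u
        od_in = draw.od_in_h if housed else draw.od_in_u
        p_surv = effective_survival(draw, side)
        ex_oud = draw.ex_oud_out_h if housed else draw.ex_oud_out_u
        ex_home_out = draw.ex_homeless_out_h if housed else draw.ex_homeless_out_u
        ex_home_in = draw.ex_homeless_in_h if housed else draw.ex_homeless_in_u
        c_od = draw.c_od_h if housed else draw.c_od_u

        for base in ("O1", "O2"):
            i = _idx(base, side)
            qol[i] = q_out
            od_rate[i] = od_out
            excess[i] = ex_oud + ex_home_out
            c_oud[i] = draw.c_oud_out
        for base in ("I", "T"):
            i = _idx(base, side)
            qol[i] = q_tr
            od_rate[i] = od_in
            c_oud[i] = draw.c_oud_in
            c_treat[i] = draw.c_treatment
        # induction: the all-cause multiplier also scales the excess term
        excess[_idx("I", side)] = draw.induction_mult * ex_home_in
        excess[_idx("T", side)] = ex_home_in
        # abstinent individuals are out of treatment: the out-of-treatment
        # excess-OUD mortality and health-care cost still apply; the
        # homelessness excess uses the (lower) in-treatment value since they
        # are not actively using
        for base in ["A1"] + [f"A2_{k}" for k in range(1, 10)]:
            i = _idx(base, side)
            excess[i] = ex_oud + ex_home_in
            c_oud[i] = draw.c_oud_out
        qol[_idx("A1", side)] = q_a1
        for k in range(1, 10):
            # the two published abstinence utilities act as levels: the
            # first-year value applies through year 10, the >=10-year value
            # from the final bin onward
            qol[_idx(f"A2_{k}", side)] = q_a10 if k == 9 else q_a1
        lo = 0 if housed else N_SIDE
        od_fatal[lo:lo + N_SIDE] = od_rate[lo:lo + N_SIDE] * (1.0 - p_surv)
        c_odev[lo:lo + N_SIDE] = od_rate[lo:lo + N_SIDE] * (c_od + draw.c_naloxone)
        if housed:
            c_house[:N_SIDE] = draw.housing_cost
        else:
            c_home[N_SIDE:N_LIVE] = draw.c_homeless

    return StateVectors(qol=qol, od_rate=od_rate, od_fatal=od_fatal,
                        excess_mort=excess, cost_oud=c_oud,
                        cost_homeless=c_home, cost_treatment=c_treat,
                        cost_od_event=c_odev, cost_housing=c_house,
                        live=LIVE_MASK.copy())


def build_edges(draw: ParameterDraw) -> tuple[np.ndarray, np.ndarray,
                                              np.ndarray, np.ndarray]:
    """Assemble the time-invariant generator edge list.

    Returns ``(from_idx, to_idx, rate, bg_mult)`` where ``bg_mult`` is the
    per-state multiplier on background mortality (1 for live states, the
    induction multiplier for the induction states, 0 for sinks).
    """
    vec = state_vectors(draw)
    edges: list[tuple[int, int, float]] = []

    for side in ("H", "U"):
        housed = side == "H"
        b = draw.entry_h if housed else draw.entry_u
        q = draw.disc_h if housed else draw.disc_u
        s = draw.succ_h if housed else draw.succ_u
        a = draw.abst_h if housed else draw.abst_u
        r1 = draw.rel1_h if housed else draw.rel1_u
        r2 = draw.rel2_h if housed else draw.rel2_u
        o1, o2 = _idx("O1", side), _idx("O2", side)
        ii, tt = _idx("I", side), _idx("T", side)
        a1 = _idx("A1", side)
        edges += [
            (o1, o2, draw.first_month_exit_rate),
            (o2, ii, b),
            (ii, tt, draw.induction_exit_rate),
            (ii, o1, q),          # induction failure, set to the quit rate
            (tt, o1, q),
            (tt, a1, s),
            (o1, a1, a),
            (o2, a1, a),
            (a1, _idx("A2_1", side), 1.0),
            (a1, o1, r1),
        ]
        for k in range(1, 10):
            ak = _idx(f"A2_{k}", side)
            if k < 9:
                edges.append((ak, _idx(f"A2_{k + 1}", side), 1.0))
            edges.append((ak, o1, r2))

    # housing loss: every housed live state to its unhoused counterpart
    group_mult = {"O1": draw.loss_mult_out, "O2": draw.loss_mult_out,
                  "I": draw.loss_mult_in, "T": draw.loss_mult_in}
    for base in _SIDE_STATES:
        mult = group_mult.get(base, draw.loss_mult_abst)
        edges.append((_idx(base, "H"), _idx(base, "U"),
                      draw.loss_rate * mult))

    # deaths: fatal overdose and non-background excess mortality
    for i in range(N_LIVE):
        if vec.od_fatal[i] > 0:
            edges.append((i, D_OD, float(vec.od_fatal[i])))
        if vec.excess_mort[i] > 0:
            edges.append((i, D_OTHER, float(vec.excess_mort[i])))

    bg_mult = LIVE_MASK.copy()
    bg_mult[_idx("I", "H")] = draw.induction_mult
    bg_mult[_idx("I", "U")] = draw.induction_mult

    ef = np.array([e[0] for e in edges], dtype=np.int64)
    et = np.array([e[1] for e in edges], dtype=np.int64)
    er = np.array([e[2] for e in edges], dtype=np.float64)
    if np.any(er < 0):
        raise ValueError("negative transition rate in generator")
    return ef, et, er, bg_mult


@dataclasses.dataclass(frozen=True)
class RateAssembly:
    """The full generator at one (stratum, time): edges plus event rates."""

    edges: tuple[tuple[str, str, float], ...]
    od_rate: np.ndarray
    od_fatal: np.ndarray
    mortality_background: np.ndarray
    mortality_excess: np.ndarray

    def rate(self, src: str, dst: str) -> float:
        i, j = state_index(src), state_index(dst)
        return sum(r for a, b, r in self.edges
                   if state_index(a) == i and state_index(b) == j)

    def total_outflow(self, src: str) -> float:
        i = state_index(src)
        out = sum(r for a, _, r in self.edges if state_index(a) == i)
        return out + float(self.mortality_background[i])


def assemble_rates(draw: ParameterDraw, stratum: CohortStratum | None = None,
                   t: float = 0.0,
                   life_table: LifeTable | None = None) -> RateAssembly:
    """Readable rate assembly for one stratum at time ``t``.

    Background mortality is evaluated at ``age_at_entry + t`` when a stratum
    and life table are given; otherwise it is zero (useful for inspecting
    the structural rates alone).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    ef, et, er, bg_mult = build_edges(draw)
    vec = state_vectors(draw)
    mu = 0.0
    if stratum is not None and life_table is not None:
        mu = background_mortality(life_table, stratum.age_at_entry + t)
    bg = bg_mult * mu
    named = tuple((STATE_NAMES[i], STATE_NAMES[j], float(r))
                  for i, j, r in zip(ef, et, er))
    return RateAssembly(edges=named, od_rate=vec.od_rate,
                        od_fatal=vec.od_fatal, mortality_background=bg,
                        mortality_excess=vec.excess_mort)


def stable_step(draw: ParameterDraw, base_step: float = 1.0 / 12.0,
                mu_max: float = 0.4) -> float:
    """Largest step <= ``base_step`` keeping RK4 inside its stability region.

    Bounds the fastest total outflow over all states assuming background
    mortality up to ``mu_max`` per year, and subdivides the base step so that
    ``step * max_outflow <= 2.0`` (comfortably inside the RK4 real-axis
    limit of about 2.785, which also avoids transient negativity in nearly
    empty compartments).
    """
    ef, _, er, bg_mult = build_edges(draw)
    outflow = np.zeros(N_STATES)
    np.add.at(outflow, ef, er)
    outflow += bg_mult * mu_max
    lam = float(outflow.max())
    n_sub = max(1, math.ceil(base_step * lam / 2.0))
    return base_step / n_sub


@dataclasses.dataclass(frozen=True)
class EventSummary:
    """Event counts per 1000 persons over a reporting window."""

    window: float
    overdoses_total: float
    overdoses_fatal: float
    overdoses_nonfatal: float
    deaths_total: float
    deaths_od: float
    deaths_other: float


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Compartment occupancy over time for every cohort stratum."""

    cohort: Cohort
    draw: ParameterDraw
    arm: str
    step: float
    times: np.ndarray          # (T,)
    occ: np.ndarray            # (n_strata, N_STATES, T)
    od_total_cum: np.ndarray   # (n_strata, T) cumulative overdoses per person
    n_steps: np.ndarray        # (n_strata,) live steps before the age cap

    def weighted(self, per_state: np.ndarray) -> np.ndarray:
        """Cohort-weighted time series of ``sum_k per_state[k]*occ[:,k,:]``."""
        w = np.array([s.weight for s in self.cohort.strata])
        return np.einsum("s,skt,k->t", w, self.occ, per_state)

    def mass_error(self) -> float:
        return float(np.abs(self.occ.sum(axis=1) - 1.0).max())


def _initial_state(arm: str) -> int:
    if arm == "status_quo":
        return _idx("O2", "U")
    if arm == "housing":
        return _idx("O2", "H")
    raise ValueError(f"unknown arm {arm!r}; expected 'status_quo' or 'housing'")


def _grid(cohort: Cohort, step: float) -> tuple[np.ndarray, int]:
    n_steps = np.array(
        [max(0, round((MAX_AGE - s.age_at_entry) / step)) for s in cohort.strata],
        dtype=np.int64)
    return n_steps, int(n_steps.max())


def integrate_cohort(cohort: Cohort, draw: ParameterDraw, arm: str,
                     step: float = 1.0 / 12.0,
                     horizon: float | None = None) -> Trajectory:
    """Integrate compartment occupancy for every stratum.

    Each stratum starts with unit mass out of treatment for more than one
    month — unhoused in the status quo, housed under the intervention — and
    is advanced with RK4 at fixed ``step`` (years) until it reaches age 100
    (or ``horizon`` years if given, whichever is sooner), after which its
    occupancy is frozen and contributes no further events.
    """
    if step > 1.0 / 12.0 + 1e-12:
        raise ValueError("step must be at most one month (1/12 year)")
    ef, et, er, bg_mult = build_edges(draw)
    mu_tab = cohort.mortality_table(MAX_AGE - min(s.age_at_entry
                                                  for s in cohort.strata))
    # very stiff draws can push RK4 outside its positivity region even when
    # stable; halve the step (deterministically) until occupancy stays
    # non-negative
    for attempt in range(5):
        n_steps, t_max = _grid(cohort, step)
        if horizon is not None:
            cap = int(round(horizon / step))
            n_steps = np.minimum(n_steps, cap)
            t_max = min(t_max, cap)
        occ = np.zeros((cohort.n_strata, N_STATES, t_max + 1))
        flag = _kernel.integrate_trajectory(_initial_state(arm), ef, et, er,
                                            bg_mult, mu_tab, n_steps, step,
                                            occ)
        if flag == 0:
            break
        step /= 2.0
    else:
        raise RuntimeError(
            "occupancy went negative during integration even after step "
            "refinement; this parameter draw needs a smaller step")
    times = np.arange(t_max + 1) * step
    vec = state_vectors(draw)
    od_rate_ts = np.einsum("skt,k->st", occ, vec.od_rate)
    od_cum = np.concatenate(
        [np.zeros((cohort.n_strata, 1)),
         np.cumsum(0.5 * step * (od_rate_ts[:, 1:] + od_rate_ts[:, :-1]),
                   axis=1)], axis=1)
    return Trajectory(cohort=cohort, draw=draw, arm=arm, step=step,
                      times=times, occ=occ, od_total_cum=od_cum,
                      n_steps=n_steps)


def summarize_events(traj: Trajectory, window: float = 5.0) -> EventSummary:
    """Stratum-weighted event counts per 1000 persons at ``t = window``."""
    if window > traj.times[-1] + 1e-9:
        raise ValueError("window exceeds the simulated horizon")
    it = int(round(window / traj.step))
    it = min(it, len(traj.times) - 1)
    w = np.array([s.weight for s in traj.cohort.strata])
    scale = 1000.0
    od_total = float(w @ traj.od_total_cum[:, it]) * scale
    deaths_od = float(w @ traj.occ[:, D_OD, it]) * scale
    deaths_other = float(w @ traj.occ[:, D_OTHER, it]) * scale
    return EventSummary(
        window=window,
        overdoses_total=od_total,
        overdoses_fatal=deaths_od,
        overdoses_nonfatal=od_total - deaths_od,
        deaths_total=deaths_od + deaths_other,
        deaths_od=deaths_od,
        deaths_other=deaths_other,
    )
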