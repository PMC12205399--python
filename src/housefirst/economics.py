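"""Discounted lifetime costs and QALYs from a simulated trajectory.

Costs take a limited societal perspective: housing cost plus all health-care
costs (background care scaled by age and sex, excess care for the disorder in
and out of treatment, excess care while unhoused, treatment, naloxone, and
per-overdose care).  Criminal-justice costs are excluded.  Quality-adjusted
life-years weight person-time by state-specific multipliers.  Both accrue
continuously with exponential discounting ``e^(-rho*t)`` via the trapezoidal
rule on the integration grid of the dynamics (no separate discretization).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dynamics import LIVE_MASK, Trajectory, EventSummary, state_vectors, \
    summarize_events
from .params import ParameterDraw

__all__ = [
    "CostBreakdown", "OutcomeSet", "ICERResult",
    "background_cost_table", "accrue_costs", "accrue_qalys",
    "outcome_set", "compare_arms",
]

COST_COMPONENTS = ("background", "excess_oud", "excess_homeless",
                   "treatment", "naloxone", "per_overdose", "housing")


@dataclasses.dataclass(frozen=True)
class CostBreakdown:
    """Discounted per-person lifetime costs, USD (2024)."""

    components: dict[str, float]

    @property
    def housing(self) -> float:
        return self.components["housing"]

    @property
    def health_care(self) -> float:
        return sum(v for k, v in self.components.items() if k != "housing")

    @property
    def total(self) -> float:
        return self.health_care + self.housing


@dataclasses.dataclass(frozen=True)
class OutcomeSet:
    """Per-person outcomes for one arm under one parameter draw."""

    qalys: float
    life_years: float
    costs: CostBreakdown
    events: EventSummary


@dataclasses.dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    flag: str  # "", "dominant", "dominated", or "undefined"


def background_cost_table(traj: Trajectory, draw: ParameterDraw) -> np.ndarray:
    """Annual background health-care cost per (stratum, simulation year).

    ``cost = base * (1 + g)^(age - 30) * sex_multiplier`` anchored at a
    30-year-old male.
    """
    n_years = int(np.ceil(traj.times[-1])) + 1
    out = np.zeros((traj.cohort.n_strata, n_years))
    for i, s in enumerate(traj.cohort.strata):
        mult = 1.0 if s.sex == "male" else draw.bg_cost_female_mult
        ages = s.age_at_entry + np.arange(n_years)
        out[i] = (draw.bg_cost_male_30
                  * (1.0 + draw.bg_cost_growth) ** (ages - 30.0) * mult)
    return out


def _year_index(traj: Trajectory, n_years: int) -> np.ndarray:
    # the age year used at grid point t is the year of the preceding step's
    # midpoint, matching the piecewise-constant convention of the integrator
    idx = np.floor((np.arange(len(traj.times)) - 0.5) * traj.step).astype(int)
    return np.clip(idx, 0, n_years - 1)


def _accrue(traj: Trajectory, series: np.ndarray, rho: float,
            window: float | None) -> float:
    """Cohort-weighted discounted trapezoidal integral of per-stratum series.

    ``series`` has shape ``(n_strata, n_times)``.  Each stratum integrates
    from 0 to the earlier of its age cap and ``window`` with trapezoid end
    weights at both ends of its own range; occupancy frozen past the cap
    accrues nothing.
    """
    n_times = len(traj.times)
    cut = n_times - 1
    if window is not None:
        cut = min(int(round(window / traj.step)), cut)
    n_eff = np.minimum(traj.n_steps, cut)[:, None]
    idx = np.arange(n_times)[None, :]
    wgt = np.where((idx > 0) & (idx < n_eff), 1.0, 0.0)
    wgt += 0.5 * (((idx == 0) | (idx == n_eff)) & (n_eff > 0))
    disc = np.exp(-rho * traj.times)[None, :]
    w = np.array([s.weight for s in traj.cohort.strata])
    return float(traj.step * (w @ (series * wgt * disc).sum(axis=1)))


def _state_series(traj: Trajectory, per_state: np.ndarray) -> np.ndarray:
    """Per-stratum time series of a per-state quantity, shape (S, T)."""
    return np.einsum("skt,k->st", traj.occ, per_state)


def accrue_costs(traj: Trajectory, draw: ParameterDraw,
                 discount_rate: float | None = None,
                 window: float | None = None) -> CostBreakdown:
    """Discounted per-person cost ledger accrued over the trajectory.

    ``window`` restricts accrual to the first ``window`` years (used for
    budget-impact reporting); the default accrues over the whole lifetime.
    """
    rho = draw.discount_rate if discount_rate is None else discount_rate
    if rho < 0:
        raise ValueError("discount rate must be non-negative")
    vec = state_vectors(draw)

    # background cost: stratum- and age-dependent
    bgc = background_cost_table(traj, draw)
    yidx = _year_index(traj, bgc.shape[1])
    bg_series = _state_series(traj, LIVE_MASK) * bgc[:, yidx]

    od_events = _state_series(traj, vec.od_rate)
    components = {
        "background": _accrue(traj, bg_series, rho, window),
        "excess_oud": _accrue(traj, _state_series(traj, vec.cost_oud),
                              rho, window),
        "excess_homeless": _accrue(
            traj, _state_series(traj, vec.cost_homeless), rho, window),
        "treatment": _accrue(traj, _state_series(traj, vec.cost_treatment),
                             rho, window),
        # one provision at entry plus one refill per overdose event
        "naloxone": draw.c_naloxone
        + _accrue(traj, od_events * draw.c_naloxone, rho, window),
        "per_overdose": _accrue(
            traj, _state_series(traj, vec.cost_od_event
                                - vec.od_rate * draw.c_naloxone),
            rho, window),
        "housing": _accrue(traj, _state_series(traj, vec.cost_housing),
                           rho, window),
    }
    for k, v in components.items():
        if v < -1e-9:
            raise ValueError(f"negative cost component {k!r}: {v}")
    return CostBreakdown(components=components)


def accrue_qalys(traj: Trajectory, draw: ParameterDraw,
                 discount_rate: float | None = None,
                 window: float | None = None) -> float:
    """Discounted quality-adjusted life-years per person."""
    rho = draw.discount_rate if discount_rate is None else discount_rate
    vec = state_vectors(draw)
    if np.any(vec.qol < 0) or np.any(vec.qol > 1):
        raise ValueError("quality-of-life multipliers must lie in [0, 1]")
    return _accrue(traj, _state_series(traj, vec.qol), rho, window)


def life_years(traj: Trajectory, discount_rate: float = 0.0) -> float:
    return _accrue(traj, _state_series(traj, LIVE_MASK), discount_rate, None)


def outcome_set(traj: Trajectory, draw: ParameterDraw,
                window: float = 5.0) -> OutcomeSet:
    """Full per-arm outcome bundle: QALYs, cost ledger, 5-year events."""
    return OutcomeSet(
        qalys=accrue_qalys(traj, draw),
        life_years=life_years(traj),
        costs=accrue_costs(traj, draw),
        events=summarize_events(traj, window),
    )


def compare_arms(sq: OutcomeSet, intervention: OutcomeSet) -> ICERResult:
    """Incremental cost per QALY gained, intervention vs status quo."""
    d_cost = intervention.costs.total - sq.costs.total
    d_qaly = intervention.qalys - sq.qalys
    if d_qaly == 0.0:
        return ICERResult(d_cost, d_qaly, None, "undefined")
    if d_qaly > 0 and d_cost < 0:
        return ICERResult(d_cost, d_qaly, d_cost / d_qaly, "dominant")
    if d_qaly < 0 and d_cost > 0:
        return ICERResult(d_cost, d_qaly, None, "dominated")
    return ICERResult(d_cost, d_qaly, d_cost / d_qaly, "")
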