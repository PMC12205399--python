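"""Budget-impact arithmetic: first-year per-person costs and city-scale totals.

Unlike the lifetime cost-effectiveness results, budget impact is reported
undiscounted: the first-year housing cost per person initially housed
(attrition back to homelessness and mortality pull it below the annual
housing rate), the first-year health-care cost per person with and without
the intervention, and linear extrapolations to a city's population of people
experiencing homelessness (annual housing cost, health-care savings,
criminal-justice savings at a flat per-person figure, and one-time
construction cost per unit).
"""

from __future__ import annotations

import dataclasses

from .dynamics import Trajectory
from .economics import accrue_costs
from .params import ParameterDraw

__all__ = ["BudgetReport", "first_year_costs", "city_extrapolation"]


@dataclasses.dataclass(frozen=True)
class BudgetReport:
    first_year_housing_cost_pp: float
    annual_healthcare_cost_pp_housed: float
    annual_healthcare_cost_pp_statusquo: float
    healthcare_savings_pp: float
    city_n_peh: int
    city_annual_housing_cost: float
    city_healthcare_savings: float
    city_cj_savings: float
    city_construction_cost: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def first_year_costs(traj_statusquo: Trajectory, traj_housing: Trajectory,
                     draw: ParameterDraw) -> dict[str, float]:
    """Undiscounted first-year accruals per person initially in the cohort.

    Housing cost accrues only over housed person-time, so attrition and
    mortality keep the first-year figure below the annual housing rate.
    """
    housed = accrue_costs(traj_housing, draw, discount_rate=0.0, window=1.0)
    statusquo = accrue_costs(traj_statusquo, draw, discount_rate=0.0,
                             window=1.0)
    return {
        "first_year_housing_cost_pp": housed.housing,
        "annual_healthcare_cost_pp_housed": housed.health_care,
        "annual_healthcare_cost_pp_statusquo": statusquo.health_care,
        "healthcare_savings_pp": statusquo.health_care - housed.health_care,
    }


def city_extrapolation(pp_values: dict[str, float], n_peh: int,
                       cj_saving_pp: float = 5000.0,
                       construction_cost_per_unit: float = 225000.0,
                       ) -> BudgetReport:
    """Scale per-person figures to a city's unhoused population (exact
    multiplication, no discounting)."""
    if n_peh <= 0:
        raise ValueError("n_peh must be positive")
    return BudgetReport(
        first_year_housing_cost_pp=pp_values["first_year_housing_cost_pp"],
        annual_healthcare_cost_pp_housed=(
            pp_values["annual_healthcare_cost_pp_housed"]),
        annual_healthcare_cost_pp_statusquo=(
            pp_values["annual_healthcare_cost_pp_statusquo"]),
        healthcare_savings_pp=pp_values["healthcare_savings_pp"],
        city_n_peh=n_peh,
        city_annual_housing_cost=(
            n_peh * pp_values["first_year_housing_cost_pp"]),
        city_healthcare_savings=n_peh * pp_values["healthcare_savings_pp"],
        city_cj_savings=n_peh * cj_saving_pp,
        city_construction_cost=n_peh * construction_cost_per_unit,
    )
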