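"""Simulated cohort construction and background mortality.

The cohort of people experiencing homelessness with opioid use disorder is
represented by deterministic age-by-sex strata: integer entry ages weighted by
a truncated-normal density per sex, scaled by the sex fractions.  The model is
an expected-value compartmental model, so strata weights fully describe the
demography — no per-person sampling is involved.

Background all-cause mortality comes from a packaged life-table fixture
(``us_life_table_synthetic.csv``, a smooth synthetic approximation to
published US period life tables built once from anchor values; see the
methods note) or, as a fallback, from a Gompertz-Makeham law
``rate = c + A*exp(B*age)`` with coefficients stored in the configuration.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LifeTable",
    "CohortStratum",
    "Cohort",
    "load_life_table",
    "gompertz_makeham_life_table",
    "background_mortality",
    "build_cohort",
]

MAX_AGE = 100


@dataclasses.dataclass(frozen=True)
class LifeTable:
    """Annual all-cause mortality rate per integer age, one sex."""

    sex: str
    ages: np.ndarray      # integers 0..MAX_AGE
    rates: np.ndarray     # per year

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.rates):
            raise ValueError("ages and rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("mortality rates must be non-negative")
        adult = self.rates[self.ages >= 35]
        if np.any(np.diff(adult) < 0):
            raise ValueError("adult mortality rates must be non-decreasing")


@dataclasses.dataclass(frozen=True)
class CohortStratum:
    sex: str
    age_at_entry: int
    weight: float


@dataclasses.dataclass(frozen=True)
class Cohort:
    strata: tuple[CohortStratum, ...]
    n_persons: int
    life_tables: dict[str, LifeTable]

    def __post_init__(self) -> None:
        total = sum(s.weight for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum weights must sum to 1, got {total}")

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def sex_fraction(self, sex: str) -> float:
        return sum(s.weight for s in self.strata if s.sex == sex)

    def mean_age(self, sex: str | None = None) -> float:
        sel = [s for s in self.strata if sex is None or s.sex == sex]
        w = sum(s.weight for s in sel)
        return sum(s.weight * s.age_at_entry for s in sel) / w

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sex": [s.sex for s in self.strata],
             "age": [s.age_at_entry for s in self.strata],
             "weight": [s.weight for s in self.strata]}
        )

    def mortality_table(self, horizon_years: int) -> np.ndarray:
        """Background mortality rate per (stratum, whole simulation year)."""
        out = np.zeros((self.n_strata, horizon_years))
        for i, s in enumerate(self.strata):
            lt = self.life_tables[s.sex]
            for y in range(horizon_years):
                out[i, y] = background_mortality(lt, s.age_at_entry + y)
        return out


# ---------------------------------------------------------------------------
# life tables

def _fixture_path() -> Path:
    return Path(str(importlib.resources.files("housefirst.data")
                    / "us_life_table_synthetic.csv"))


def load_life_table(path: str | Path | None = None,
                    sex: str = "male") -> LifeTable:
    """Load one sex's life table from a ``sex,age,rate`` CSV.

    Defaults to the packaged synthetic approximation of US period life
    tables.  The lookup is capped at age 100.
    """
    df = pd.read_csv(path if path is not None else _fixture_path())
    sub = df[df["sex"] == sex].sort_values("age")
    if sub.empty:
        raise ValueError(f"no rows for sex {sex!r} in life table")
    return LifeTable(sex=sex, ages=sub["age"].to_numpy(),
                     rates=sub["rate"].to_numpy(dtype=float))


def gompertz_makeham_life_table(sex: str, c: float, A: float, B: float,
                                max_age: int = MAX_AGE) -> LifeTable:
    """Fully synthetic life table from a Gompertz-Makeham law."""
    ages = np.arange(max_age + 1)
    return LifeTable(sex=sex, ages=ages, rates=c + A * np.exp(B * ages))


def background_mortality(lt: LifeTable, age: float) -> float:
    """Annual background mortality rate at ``age`` (piecewise constant).

    Integer-age lookup (floor); ages beyond the table are capped at the
    oldest tabulated value.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    idx = min(int(np.floor(age)), len(lt.ages) - 1)
    return float(lt.rates[idx])


# ---------------------------------------------------------------------------
# cohort construction

def build_cohort(
    n: int = 1000,
    sex_fractions: tuple[float, float] = (0.70, 0.30),
    age_params: dict[str, tuple[float, float]] | None = None,
    age_bounds: tuple[int, int] = (18, 89),
    life_tables: dict[str, LifeTable] | None = None,
) -> Cohort:
    """Build deterministic age-by-sex strata by truncated-normal quadrature.

    ``sex_fractions`` is ``(male, female)`` and must sum to 1; ``age_params``
    maps sex to ``(mean, sd)``.  Weights at each integer age are proportional
    to the truncated-normal density, renormalized per sex and scaled by the
    sex fraction, so they are invariant to ``n``.  Because truncation at the
    entry-age bounds shifts the realized mean (the lower bound cuts more of
    the distribution than the upper), the location parameter is calibrated so
    the realized weighted mean age equals the requested mean.
    """
    if age_params is None:
        age_params = {"male": (46.4, 14.0), "female": (46.5, 14.3)}
    lo, hi = age_bounds
    if lo > hi:
        raise ValueError(f"age bounds inverted: {age_bounds}")
    if abs(sum(sex_fractions) - 1.0) > 1e-9:
        raise ValueError("sex fractions must sum to 1")

    if life_tables is None:
        life_tables = {s: load_life_table(sex=s) for s in ("male", "female")}

    ages = np.arange(lo, hi + 1)
    strata: list[CohortStratum] = []
    for sex, frac in zip(("male", "female"), sex_fractions):
        if frac <= 0:
            continue
        mean, sd = age_params[sex]
        if sd <= 0:
            raise ValueError(f"age SD must be positive for {sex}")
        loc = _calibrated_location(ages, mean, sd)
        dens = stats.norm.pdf(ages, loc=loc, scale=sd)
        if dens.sum() == 0:  # SD -> 0 limit: all mass on the nearest age
            dens = (ages == int(np.clip(round(mean), lo, hi))).astype(float)
        w = frac * dens / dens.sum()
        strata.extend(CohortStratum(sex, int(a), float(wi))
                      for a, wi in zip(ages, w) if wi > 0)
    return Cohort(strata=tuple(strata), n_persons=n, life_tables=life_tables)


def _calibrated_location(ages: np.ndarray, mean: float, sd: float) -> float:
    """Normal location whose truncated, integer-age mean equals ``mean``."""

    def excess(loc: float) -> float:
        d = stats.norm.pdf(ages, loc=loc, scale=sd)
        s = d.sum()
        return float((ages @ d) / s - mean) if s > 0 else np.nan

    lo, hi = mean - 3 * sd, mean + sd
    f_lo, f_hi = excess(lo), excess(hi)
    if not (np.isfinite(f_lo) and np.isfinite(f_hi)) or f_lo * f_hi >= 0:
        return mean  # degenerate SD or target outside the grid: no shift
    from scipy.optimize import brentq
    return float(brentq(excess, lo, hi, xtol=1e-9))
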