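import dataclasses

import numpy as np
import pytest

import housefirst as hf
from housefirst.cohort import LifeTable
from housefirst.params import SAMPLED_FIELDS

#: number of PSA draws used by the test profile (enough for stable means;
#: the published intervals are an order of magnitude wider than the
#: Monte-Carlo error of these means)
N_TEST_DRAWS = 200
TEST_SEED = 1


@pytest.fixture(scope="session")
def ps():
    return hf.load_parameter_set()


@pytest.fixture(scope="session")
def cohort():
    return hf.build_cohort()


@pytest.fixture(scope="session")
def bdraw(ps):
    return hf.base_draw(ps)


@pytest.fixture(scope="session")
def traj_pair(cohort, bdraw):
    return {arm: hf.integrate_cohort(cohort, bdraw, arm)
            for arm in ("status_quo", "housing")}


@pytest.fixture(scope="session")
def base_psa(ps, cohort):
    return hf.run_psa(ps, cohort, N_TEST_DRAWS, TEST_SEED)


def zero_life_tables():
    ages = np.arange(101)
    return {s: LifeTable(sex=s, ages=ages, rates=np.zeros(101))
            for s in ("male", "female")}


def single_stratum_cohort(age=30.0, zero_mortality=True):
    """One male stratum at a fixed entry age."""
    lt = zero_life_tables() if zero_mortality else None
    return hf.build_cohort(n=1000, sex_fractions=(1.0, 0.0),
                           age_params={"male": (age, 1e-9),
                                       "female": (age, 1e-9)},
                           life_tables=lt)


def make_draw(ps, **overrides):
    """Base-value draw with selected fields replaced."""
    return dataclasses.replace(hf.base_draw(ps), **overrides)


def zero_draw(ps, **overrides):
    """Draw with every rate, cost, and multiplier zeroed (null dynamics)."""
    zeros = {name: 0.0 for name in SAMPLED_FIELDS}
    zeros.update(dict(first_month_exit_rate=0.0, induction_exit_rate=0.0,
                      bg_cost_male_30=0.0, bg_cost_growth=0.0,
                      # keep witnessing at the reference so the sampled
                      # survival probability applies unchanged
                      witness_h=0.6, witness_u=0.6,
                      witness_ref=0.6, witness_risk_ratio=3.0))
    zeros.update(overrides)
    return dataclasses.replace(hf.base_draw(ps), **zeros)
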