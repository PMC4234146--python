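import numpy as np
import pytest

from wamindex import Cohort, GeneratorConfig, HouseholdRecord, generate


def make_record(household_id="h1", site="S1", haz=-1.0, assets=None, **kwargs):
    """A complete household record with overridable fields."""
    defaults = dict(
        child_age_months=36,
        child_sex=1,
        maternal_education_years=6,
        income_local=100.0,
        currency="USD",
        people_per_room=1.5,
        improved_water=1,
        improved_sanitation=1,
        any_child_died=0,
        electricity=1,
        natural_flooring=0,
        solid_cooking_fuel=0,
    )
    defaults.update(kwargs)
    if assets is None:
        assets = {"radio": 1, "tv": 0, "fridge": 1}
    return HouseholdRecord(household_id=household_id, site=site, haz=haz,
                           assets=assets, **defaults)


@pytest.fixture
def three_households():
    return Cohort(records=[
        make_record("h1", "S1", haz=-2.5),
        make_record("h2", "S1", haz=0.2, assets={"radio": 0, "tv": 1, "fridge": 0}),
        make_record("h3", "S2", haz=-1.1, assets={"radio": 1, "tv": 1, "fridge": 1}),
    ])


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    cohort, truth = generate(GeneratorConfig(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def haz_of():
    def _haz(cohort):
        return np.array([r.haz for r in cohort], dtype=float)

    return _haz
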