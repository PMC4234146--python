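import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wamindex import (IncomeOctileCutoffs, MpiCutoffs, compute_index,
                      education_measure, education_score, income_octile_score,
                      mpi_wealth, wami, water_sanitation_score)
from wamindex.survey_data import Cohort
from conftest import make_record

EIGHT_ASSETS = [f"a{j}" for j in range(8)]


def household(n_assets=8, education=16, income=500.0, water=1, sanitation=1,
              **kwargs):
    assets = {a: int(j < n_assets) for j, a in enumerate(EIGHT_ASSETS)}
    return make_record(assets=assets, maternal_education_years=education,
                       income_local=income, improved_water=water,
                       improved_sanitation=sanitation, **kwargs)


class TestComponents:
    @pytest.mark.parametrize("years", [0, 10, 16])
    def test_education_measure_is_identity(self, years):
        assert education_measure(years) == years

    @pytest.mark.parametrize("years,points", [(16, 8), (0, 0), (18, 8), (7, 3.5)])
    def test_education_score_halves_capped_years(self, years, points):
        assert education_score(years) == points

    def test_negative_years_rejected(self):
        with pytest.raises(ValueError):
            education_score(-1)

    @pytest.mark.parametrize("w,s,points", [(1, 1, 8), (1, 0, 4), (0, 1, 4), (0, 0, 0)])
    def test_water_sanitation_four_points_each(self, w, s, points):
        assert water_sanitation_score(w, s) == points

    @pytest.mark.parametrize("income,score", [
        (100, 4),      # inside the 72.01-106 band
        (26.00, 1),    # octile upper bounds are inclusive
        (26.01, 2),
        (500, 8),      # open-ended top bin
        (0, 1),
        (293.0, 7), (293.01, 8),
    ])
    def test_income_octiles(self, income, score):
        assert income_octile_score(income) == score

    def test_income_negative_rejected(self):
        with pytest.raises(ValueError):
            income_octile_score(-5)

    def test_octile_score_is_nondecreasing_step_with_eight_levels(self):
        grid = np.arange(0, 400, 0.25)
        scores = np.array([income_octile_score(v) for v in grid])
        assert np.all(np.diff(scores) >= 0)
        assert set(scores) == set(range(1, 9))

    def test_empirical_cutoffs_split_sample_into_octiles(self):
        rng = np.random.default_rng(0)
        incomes = np.round(np.exp(rng.normal(4.5, 0.8, size=800)), 2)
        cutoffs = IncomeOctileCutoffs.from_sample(incomes)
        scores = np.array([income_octile_score(v, cutoffs) for v in incomes])
        counts = np.bincount(scores, minlength=9)[1:]
        assert counts.min() > 60 and counts.max() < 140


class TestWami:
    def test_all_maxima_scores_one(self):
        c = wami(household(), EIGHT_ASSETS)
        assert (c.water_san_score, c.asset_score, c.education_score,
                c.income_score) == (8, 8, 8, 8)
        assert c.total == 32 and c.wami == 1.0

    def test_floor_is_one_thirtysecond(self):
        # the income component never scores 0, so WAMI bottoms out at 1/32
        c = wami(household(n_assets=0, education=0, income=10.0,
                           water=0, sanitation=0), EIGHT_ASSETS)
        assert c.total == 1
        assert c.wami == pytest.approx(1 / 32)

    def test_mid_example_hand_computed(self):
        c = wami(household(n_assets=4, education=8, income=100.0,
                           water=1, sanitation=0), EIGHT_ASSETS)
        assert (c.water_san_score, c.asset_score, c.education_score,
                c.income_score) == (4, 4, 4, 4)
        assert c.wami == 0.5

    def test_missing_component_named(self):
        record = household()
        record.improved_water = None
        with pytest.raises(ValueError, match="improved_water"):
            wami(record, EIGHT_ASSETS)

    @given(
        assets=st.integers(0, 8), years=st.integers(0, 16),
        income=st.floats(0, 1000, allow_nan=False),
        water=st.integers(0, 1), sanitation=st.integers(0, 1),
    )
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_every_component(self, assets, years, income, water,
                                         sanitation):
        base = wami(household(assets, years, income, water, sanitation),
                    EIGHT_ASSETS).wami
        bumps = [
            household(min(assets + 1, 8), years, income, water, sanitation),
            household(assets, min(years + 1, 16), income, water, sanitation),
            household(assets, years, income + 50, water, sanitation),
            household(assets, years, income, 1, sanitation),
            household(assets, years, income, water, 1),
        ]
        for bumped in bumps:
            assert wami(bumped, EIGHT_ASSETS).wami >= base
        assert 1 / 32 <= base <= 1.0


class TestMpi:
    def wealthy(self):
        return make_record(
            assets={a: 1 for a in MpiCutoffs().asset_list},
            maternal_education_years=10, any_child_died=0, electricity=1,
            improved_water=1, improved_sanitation=1, natural_flooring=0,
            solid_cooking_fuel=0)

    def deprived(self):
        return make_record(
            assets={a: 0 for a in MpiCutoffs().asset_list},
            maternal_education_years=2, any_child_died=1, electricity=0,
            improved_water=0, improved_sanitation=0, natural_flooring=1,
            solid_cooking_fuel=1)

    def test_no_deprivation_scores_one(self):
        assert mpi_wealth(self.wealthy()) == 1.0

    def test_full_deprivation_scores_zero(self):
        assert mpi_wealth(self.deprived()) == 0.0

    def test_education_only_deprivation_is_two_thirds(self):
        record = self.wealthy()
        record.maternal_education_years = 3
        assert mpi_wealth(record) == pytest.approx(2 / 3)

    def test_living_standard_block_is_exchangeable(self):
        # one deprivation anywhere in the six living-standard items
        # costs the same 1/18 of the deprivation score
        base = self.wealthy()
        variants = []
        for flag in ("electricity", "improved_water", "improved_sanitation"):
            record = self.wealthy()
            setattr(record, flag, 0)
            variants.append(mpi_wealth(record))
        for flag in ("natural_flooring", "solid_cooking_fuel"):
            record = self.wealthy()
            setattr(record, flag, 1)
            variants.append(mpi_wealth(record))
        assert all(v == pytest.approx(1 - 1 / 18) for v in variants)

    def test_asset_count_threshold(self):
        record = self.wealthy()
        for name in list(MpiCutoffs().asset_list)[2:]:
            record.assets[name] = 0  # owns exactly 2 of 7 -> not deprived
        assert mpi_wealth(record) == 1.0
        record.assets[MpiCutoffs().asset_list[1]] = 0  # owns 1 -> deprived
        assert mpi_wealth(record) == pytest.approx(1 - 1 / 18)

    def test_missing_field_named(self):
        record = self.wealthy()
        record.any_child_died = None
        with pytest.raises(ValueError, match="any_child_died"):
            mpi_wealth(record)


class TestComputeIndex:
    def cohort(self):
        return Cohort(records=[
            household(3, education=4, haz=-2.2, household_id="h1"),
            household(6, education=9, haz=-0.5, household_id="h2"),
            household(8, education=12, haz=0.3, household_id="h3"),
        ])

    def test_education_scores_equal_years(self):
        index = compute_index(self.cohort(), "education")
        assert list(index.scores) == [4, 9, 12]

    def test_wami_composition(self):
        index = compute_index(self.cohort(), "wami",
                              {"selected_assets": EIGHT_ASSETS})
        assert index.components is not None
        assert [c.asset_score for c in index.components] == [3, 6, 8]
        assert np.all((index.scores >= 1 / 32) & (index.scores <= 1))

    def test_missing_context_states_required_fit(self):
        with pytest.raises(ValueError, match="loadings"):
            compute_index(self.cohort(), "pca")
        with pytest.raises(ValueError, match="asset set"):
            compute_index(self.cohort(), "rf_assets")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            compute_index(self.cohort(), "dhs_quintile")
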