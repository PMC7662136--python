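import numpy as np
import pytest

import schoolyll as sy
from schoolyll.education_yll import MAX_AGE_OF_DEATH

from conftest import brute_force_expectancy

EFFECT = sy.AttainmentEffect()
MORT = sy.EducationMortalityEffect()
POINT_MORT = sy.EducationMortalityEffect(rr_ci=(0.75, 0.75))  # rr_sd = 0


class TestAttainmentStage:
    def test_zero_days_zero_loss(self):
        assert np.all(sy.attainment_loss_draws(0.0, "male", EFFECT, 100, seed=0) == 0.0)

    @pytest.mark.parametrize(
        "sex,central", [("male", 54 * 0.0262 / 10), ("female", 54 * 0.0217 / 10)]
    )
    def test_median_closure_central_values(self, sex, central):
        draws = sy.attainment_loss_draws(54.0, sex, EFFECT, 100_000, seed=2)
        assert draws.mean() == pytest.approx(central, abs=0.003)
        assert draws.min() >= 0.0

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            sy.attainment_loss_draws(54.0, "unknown", EFFECT, 10, seed=0)

    def test_rr_sd_from_symmetric_ci(self):
        assert MORT.rr_sd == pytest.approx((0.90 - 0.60) / (2 * 1.96), rel=1e-3)


class TestHazardMultiplier:
    def test_zero_loss_is_unity(self):
        assert sy.hazard_multiplier(0.75, 0.0) == 1.0

    def test_one_lost_year_is_reciprocal(self):
        assert sy.hazard_multiplier(0.75, 1.0) == pytest.approx(4.0 / 3.0)

    def test_log_arithmetic(self):
        assert sy.hazard_multiplier(0.75, 0.1415) == pytest.approx(
            np.exp(0.1415 * np.log(1 / 0.75)), rel=1e-12
        )

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            sy.hazard_multiplier(0.0, 0.1)


class TestPerChild:
    def test_multiplier_one_costs_nothing(self, male_table):
        assert sy.per_child_yll(male_table, 8, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_toy_table_against_enumeration(self):
        q = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.05, 0.1, 0.2, 0.5, 1.0])
        lt = sy.build_life_table(np.arange(10), q, "male")
        mult, age = 1.25, 6
        q_adj = q.copy()
        q_adj[age:] = np.minimum(1.0, q_adj[age:] * mult)
        for rate in (0.0, 0.03):
            expected = brute_force_expectancy(q, age, rate) - brute_force_expectancy(
                q_adj, age, rate
            )
            assert sy.per_child_yll(lt, age, mult, rate) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_for_hazard_increase(self, male_table):
        assert sy.per_child_yll(male_table, 5, 1.1) > 0.0

    def test_draws_collapse_to_point_computation(self, male_table):
        point = sy.AttainmentEffect(male_se=0.0, female_se=0.0)
        draws = sy.per_child_yll_draws(
            male_table, 8, 54.0, "male", point, POINT_MORT, 50, seed=3
        )
        mult = sy.hazard_multiplier(0.75, 54 * 0.0262 / 10)
        capped = male_table.truncate(MAX_AGE_OF_DEATH)
        assert np.allclose(draws, sy.per_child_yll(capped, 8, mult), atol=1e-12)


class TestPopulation:
    def test_empty_population_all_zero(self, small_population, default_tables):
        empty = sy.ChildPopulation(
            small_population.df.iloc[:0], small_population.closure_days
        )
        draws = sy.population_education_yll(empty, EFFECT, MORT, default_tables, 0.0, 50, seed=1)
        assert np.all(draws == 0.0)

    def test_linearity_in_counts(self, small_population, default_tables):
        doubled = sy.ChildPopulation(
            small_population.df.assign(count=small_population.df["count"] * 2),
            small_population.closure_days,
        )
        a = sy.population_education_yll(
            small_population, EFFECT, MORT, default_tables, 0.0, 200, seed=5
        )
        b = sy.population_education_yll(doubled, EFFECT, MORT, default_tables, 0.0, 200, seed=5)
        assert np.allclose(b, 2 * a, rtol=1e-12)

    def test_degenerate_params_match_hand_computation(self, small_population, default_tables):
        point = sy.AttainmentEffect(male_se=0.0, female_se=0.0)
        draws = sy.population_education_yll(
            small_population, point, POINT_MORT, default_tables, 0.0, 3, seed=0
        )
        coef = {"male": 0.0262, "female": 0.0217}
        expected = 0.0
        for row in small_population.df.itertuples():
            days = small_population.closure_days[row.state]
            mult = sy.hazard_multiplier(0.75, days / 10 * coef[row.sex])
            lt = default_tables[(row.sex, row.race)].truncate(MAX_AGE_OF_DEATH)
            expected += row.count * sy.per_child_yll(lt, row.age, mult)
        assert np.allclose(draws, expected, rtol=1e-9)

    def test_monotone_in_closure_days(self, small_population, default_tables):
        short = sy.ChildPopulation(
            small_population.df, small_population.closure_days * 0 + 40
        )
        long = sy.ChildPopulation(
            small_population.df, small_population.closure_days * 0 + 70
        )
        a = sy.population_education_yll(short, EFFECT, MORT, default_tables, 0.0, 400, seed=9)
        b = sy.population_education_yll(long, EFFECT, MORT, default_tables, 0.0, 400, seed=9)
        assert np.median(b) > np.median(a)
        assert np.mean(b > a) > 0.99  # same draws, more days -> more loss

    def test_discount_monotonicity(self, small_population, default_tables):
        out = sy.population_education_yll_multi(
            small_population, EFFECT, MORT, default_tables, (0.0, 0.005, 0.03), 400, seed=11
        )
        med = np.median(out, axis=0)
        assert med[0] > med[1] > med[2]

    def test_negative_draws_are_rare(self, small_population, default_tables):
        # only rr > 1 draws (prob ~6e-4) produce (small) negative totals
        draws = sy.population_education_yll(
            small_population, EFFECT, MORT, default_tables, 0.0, 5000, seed=13
        )
        assert np.mean(draws < 0) < 0.005

    def test_adult_onset_loses_less(self, small_population, default_tables):
        child = sy.population_education_yll(
            small_population, EFFECT, MORT, default_tables, 0.0, 200, seed=17
        )
        adult = sy.population_education_yll(
            small_population, EFFECT, MORT, default_tables, 0.0, 200, seed=17,
            rr_from_age="adult",
        )
        assert np.all(adult <= child + 1e-9)

    def test_missing_stratum_table_rejected(self, small_population):
        tables = {("male", "All"): sy.default_life_tables()[("male", "All")]}
        with pytest.raises(KeyError):
            sy.population_education_yll(
                small_population, EFFECT, MORT, tables, 0.0, 10, seed=0
            )


def test_population_csv_round_trip(tmp_path, small_population):
    pop_path, clo_path = tmp_path / "pop.csv", tmp_path / "closure.csv"
    small_population.to_csv(pop_path, clo_path)
    back = sy.ChildPopulation.from_csv(pop_path, clo_path)
    assert back.total_count() == small_population.total_count()
    assert (back.closure_days == small_population.closure_days).all()


def test_population_validation(small_population):
    bad_age = small_population.df.copy()
    bad_age.loc[0, "age"] = 14
    with pytest.raises(ValueError):
        sy.ChildPopulation(bad_age, small_population.closure_days)
    with pytest.raises(ValueError):
        sy.ChildPopulation(small_population.df, small_population.closure_days * 0 - 1)
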