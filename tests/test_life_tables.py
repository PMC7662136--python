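import numpy as np
import pytest

import schoolyll as sy
from schoolyll.life_tables import GompertzMakehamParams

from conftest import brute_force_expectancy


class TestBuildAndExpectancy:
    def test_immediate_death_gives_half_year(self):
        lt = sy.build_life_table([0], [1.0], "male")
        assert sy.remaining_life(lt, 0) == 0.5

    def test_constant_hazard_geometric_series(self):
        # q = 0.5 forever: e(0) = sum 0.5^t + 0.5 = 1.5
        q = np.full(80, 0.5)
        q[-1] = 1.0
        lt = sy.build_life_table(np.arange(80), q, "female")
        assert sy.remaining_life(lt, 0) == pytest.approx(1.5, abs=1e-6)

    @pytest.mark.parametrize("age", [0, 1, 2, 3])
    def test_toy_table_matches_exhaustive_enumeration(self, toy_q, age):
        lt = sy.build_life_table(np.arange(4), toy_q, "male")
        assert sy.remaining_life(lt, age) == pytest.approx(
            brute_force_expectancy(toy_q, age), abs=1e-12
        )

    def test_terminal_age_half_year(self, male_table):
        assert sy.remaining_life(male_table, male_table.omega) == 0.5

    def test_yearly_gain_bounded(self, male_table):
        # cannot gain more than one year of expectancy per year survived
        assert np.all(np.diff(male_table.ex) <= 1.0 + 1e-12)

    def test_validation_rejects_bad_q(self):
        with pytest.raises(ValueError):
            sy.build_life_table([0, 1], [0.5, 0.5], "male")  # terminal q != 1
        with pytest.raises(ValueError):
            sy.build_life_table([0, 1], [1.5, 1.0], "male")
        with pytest.raises(ValueError):
            sy.remaining_life(sy.build_life_table([0], [1.0], "male"), 5)


class TestAnchorReconstruction:
    def test_printed_anchors_reproduced(self, male_table, female_table):
        anchors = sy.builtin_expectancy_anchors()
        for lt, anch in ((male_table, anchors["male"]), (female_table, anchors["female"])):
            for age, ex in zip(anch.ages, anch.ex):
                assert lt.ex[age] == pytest.approx(ex, abs=0.2)

    def test_life_expectancy_at_birth(self, male_table, female_table):
        assert sy.remaining_life(male_table, 0) == pytest.approx(76.0, abs=0.2)
        assert sy.remaining_life(female_table, 0) == pytest.approx(81.0, abs=0.2)

    def test_gompertz_makeham_round_trip(self):
        # anchors generated from a known GM table -> parameters recovered
        true = GompertzMakehamParams(a=6e-4, b=3e-5, c=0.095)
        ages = np.arange(101)
        q = true.annual_q(ages)
        q[-1] = 1.0
        lt = sy.build_life_table(ages, q, "male")
        anchor_ages = (0, 1, 10, 20, 30, 40, 50, 60, 70, 80, 85)
        anch = sy.ExpectancyAnchors(
            "male", anchor_ages, tuple(float(lt.ex[a]) for a in anchor_ages)
        )
        fit = sy.fit_gompertz_makeham(anch)
        assert fit.a == pytest.approx(true.a, rel=0.01)
        assert fit.b == pytest.approx(true.b, rel=0.01)
        assert fit.c == pytest.approx(true.c, rel=0.01)

    def test_anchor_extraction_is_fixed_point(self, male_table):
        ages = (0, 1, 10, 20, 30, 40, 50, 60, 70, 80, 85)
        anch = sy.ExpectancyAnchors(
            "male", ages, tuple(float(male_table.ex[a]) for a in ages)
        )
        rebuilt = sy.from_anchors(anch)
        for a in ages:
            assert rebuilt.ex[a] == pytest.approx(male_table.ex[a], abs=0.05)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValueError):
            sy.ExpectancyAnchors("male", (0, 10, 20, 85), (76.0, 66.0, 67.0, 5.9))
        with pytest.raises(ValueError):
            sy.ExpectancyAnchors("male", (0, 10, 20), (76.0, 66.0, 56.0))  # no 85 span


class TestHazardAdjustment:
    def test_multiplier_one_is_identity(self, male_table):
        adjusted = sy.adjust_hazard(male_table, 1.0, from_age=8)
        assert np.array_equal(adjusted.qx, male_table.qx)
        assert np.array_equal(adjusted.ex, male_table.ex)

    def test_toy_table_against_enumeration(self, toy_q):
        lt = sy.build_life_table(np.arange(4), toy_q, "male")
        adjusted = sy.adjust_hazard(lt, 1.3, from_age=1)
        q_hand = toy_q.copy()
        q_hand[1:] = np.minimum(1.0, q_hand[1:] * 1.3)
        for age in range(4):
            assert sy.remaining_life(adjusted, age) == pytest.approx(
                brute_force_expectancy(q_hand, age), abs=1e-12
            )

    def test_monotone_in_multiplier(self, male_table):
        a1 = sy.adjust_hazard(male_table, 1.2, from_age=10)
        a2 = sy.adjust_hazard(male_table, 1.4, from_age=10)
        assert np.all(a2.ex[10:-1] < a1.ex[10:-1])
        # death probabilities below from_age are untouched (expectancies
        # there still drop, since they look ahead at the raised hazard)
        assert np.array_equal(a2.qx[:10], male_table.qx[:10])
        assert np.all(a2.ex[:10] < male_table.ex[:10])

    def test_nonpositive_multiplier_rejected(self, male_table):
        with pytest.raises(ValueError):
            sy.adjust_hazard(male_table, 0.0)


class TestDiscounting:
    def test_rate_zero_equals_plain_expectancy(self, male_table):
        for age in (0, 8, 40, 85):
            assert sy.discounted_remaining_life(male_table, age, 0.0) == pytest.approx(
                sy.remaining_life(male_table, age), abs=1e-9
            )

    def test_certain_survival_annuity(self):
        # survive exactly T years then die: discounted life = annuity + 0.5
        T, r = 10, 0.03
        q = np.zeros(T + 1)
        q[-1] = 1.0
        lt = sy.build_life_table(np.arange(T + 1), q, "male")
        annuity = sum((1 + r) ** (-t) for t in range(1, T + 1))
        assert sy.discounted_remaining_life(lt, 0, r) == pytest.approx(annuity + 0.5)

    def test_monotone_in_rate(self, male_table):
        vals = [sy.discounted_remaining_life(male_table, 8, r) for r in (0.0, 0.005, 0.03, 0.1)]
        assert vals == sorted(vals, reverse=True)

    def test_huge_rate_leaves_half_year(self, male_table):
        assert sy.discounted_remaining_life(male_table, 8, 1e9) == pytest.approx(0.5)

    def test_toy_table_against_enumeration(self, toy_q):
        lt = sy.build_life_table(np.arange(4), toy_q, "male")
        for rate in (0.0, 0.03, 0.25):
            assert sy.discounted_remaining_life(lt, 0, rate) == pytest.approx(
                brute_force_expectancy(toy_q, 0, rate), abs=1e-12
            )

    def test_negative_rate_rejected(self, male_table):
        with pytest.raises(ValueError):
            sy.discounted_remaining_life(male_table, 8, -0.01)


class TestCsvRoundTrips:
    def test_life_table_round_trip(self, tmp_path, male_table, female_table):
        path = tmp_path / "lt.csv"
        sy.life_tables.write_life_table_csv([male_table, female_table], path)
        back = sy.life_tables.read_life_table_csv(path)
        assert len(back) == 2
        assert np.allclose(back[0].qx, male_table.qx)
        assert back[0].sex == "male"

    def test_anchors_round_trip(self, tmp_path):
        anchors = list(sy.builtin_expectancy_anchors().values())
        path = tmp_path / "anchors.csv"
        sy.life_tables.write_anchors_csv(anchors, path)
        assert sy.life_tables.read_anchors_csv(path) == anchors

    def test_strict_headers(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age,qx\n0,1.0\n")
        with pytest.raises(ValueError):
            sy.life_tables.read_life_table_csv(path)
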