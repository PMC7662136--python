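import numpy as np
import pytest

import schoolyll as sy


def brute_force_expectancy(q, age=0, rate=0.0):
    """Exhaustive enumeration over death-age outcomes for a small table.

    Death in the k-th year after ``age`` (k = 0, 1, ...) contributes the
    discounted value of k whole survived years plus an undiscounted half
    year, weighted by the probability of that outcome.
    """
    q = np.asarray(q, dtype=float)
    assert q[-1] == 1.0
    total, alive = 0.0, 1.0
    for k in range(age, q.size):
        p_die = alive * q[k]
        years = sum((1.0 + rate) ** (-t) for t in range(1, k - age + 1)) + 0.5
        total += p_die * years
        alive *= 1.0 - q[k]
    return total


@pytest.fixture(scope="session")
def toy_q():
    """4-age toy death probabilities with certain death at the end."""
    return np.array([0.1, 0.3, 0.6, 1.0])


@pytest.fixture(scope="session")
def male_table():
    return sy.from_anchors(sy.builtin_expectancy_anchors()["male"])


@pytest.fixture(scope="session")
def female_table():
    return sy.from_anchors(sy.builtin_expectancy_anchors()["female"])


@pytest.fixture(scope="session")
def death_table():
    return sy.builtin_death_table()


@pytest.fixture(scope="session")
def default_tables():
    return sy.default_life_tables()


@pytest.fixture(scope="session")
def small_population():
    """Down-scaled child population (same structure, 1/1000 the size)."""
    spec = sy.PopulationSpec(
        total_children=24_200,
        race_counts=(
            ("White", 11_400),
            ("Hispanic", 4_300),
            ("Black", 3_600),
            ("Other", 4_900),
        ),
    )
    return sy.generate_population(spec, seed=7)
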