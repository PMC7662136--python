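"""Synthetic inputs emulating the model's public data sources.

Nothing is downloaded: the child population emulates ACS-style enrollment
counts (24.2 million public-school children aged 5-11 with the published
race/ethnicity split), per-state closure durations reproduce the published
median and interquartile range, and life tables are reconstructed from the
remaining-life-expectancy anchors printed alongside the death table. The
age-banded COVID-19 death table itself is bundled verbatim.

What the generator deliberately does *not* emulate: real state-by-state
closure orders (only the national median/IQR is published), within-state
heterogeneity, non-uniform age structure within 5-11, and any correlation
between state size and closure length.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .direct_yll import DeathBandTable
from .education_yll import CHILD_AGES, ChildPopulation
from .life_tables import ExpectancyAnchors, LifeTable, from_anchors
from .mc_engine import rng_for

__all__ = [
    "PopulationSpec",
    "STATE_WEIGHTS",
    "generate_population",
    "generate_closure_days",
    "builtin_death_table",
    "builtin_expectancy_anchors",
    "default_life_tables",
]

# Bundled state share vector (50 states + DC): approximate shares of the US
# child population, normalized at use. Any other 51-vector may be supplied
# through PopulationSpec.state_weights.
STATE_WEIGHTS: dict[str, float] = {
    "CA": 11.9, "TX": 8.9, "FL": 6.5, "NY": 5.9, "PA": 3.9, "IL": 3.8,
    "OH": 3.5, "GA": 3.2, "NC": 3.2, "MI": 3.0, "NJ": 2.7, "VA": 2.6,
    "WA": 2.3, "AZ": 2.2, "MA": 2.1, "TN": 2.1, "IN": 2.0, "MO": 1.9,
    "MD": 1.8, "WI": 1.8, "CO": 1.7, "MN": 1.7, "SC": 1.6, "AL": 1.5,
    "LA": 1.4, "KY": 1.4, "OR": 1.3, "OK": 1.2, "CT": 1.1, "UT": 1.0,
    "IA": 1.0, "NV": 0.9, "AR": 0.9, "MS": 0.9, "KS": 0.9, "NM": 0.6,
    "NE": 0.6, "WV": 0.55, "ID": 0.55, "HI": 0.43, "NH": 0.41, "ME": 0.41,
    "MT": 0.33, "RI": 0.32, "DE": 0.30, "SD": 0.27, "ND": 0.23, "AK": 0.22,
    "DC": 0.21, "VT": 0.19, "WY": 0.18,
}

# Age-banded COVID-19 deaths through June 3, 2020 (band midpoint ages; the
# 10-year CDC bands are labelled by midpoint since the band expectancies
# match e(midpoint); 85 is the maximum age of death). Columns per sex:
# (deaths, annual death probability, remaining life expectancy).
_DEATH_ROWS: list[tuple[int, str, int, float, float]] = [
    (0, "male", 3, 0.0063, 76.0),
    (1, "male", 1, 0.0004, 75.5),
    (10, "male", 10, 0.0001, 66.5),
    (20, "male", 68, 0.0011, 56.9),
    (30, "male", 396, 0.0019, 47.7),
    (40, "male", 1094, 0.0025, 38.6),
    (50, "male", 3009, 0.0050, 29.7),
    (60, "male", 6988, 0.0115, 21.6),
    (70, "male", 11479, 0.0229, 14.4),
    (80, "male", 12961, 0.0582, 8.3),
    (85, "male", 11566, 0.0979, 5.9),
    (0, "female", 2, 0.0052, 81.0),
    (1, "female", 2, 0.0003, 80.4),
    (10, "female", 2, 0.0001, 71.5),
    (20, "female", 38, 0.0004, 61.6),
    (30, "female", 187, 0.0008, 52.0),
    (40, "female", 430, 0.0014, 42.5),
    (50, "female", 1229, 0.0031, 33.2),
    (60, "female", 3598, 0.0069, 24.6),
    (70, "female", 6881, 0.0153, 16.5),
    (80, "female", 10650, 0.0428, 9.7),
    (85, "female", 17647, 0.0743, 7.0),
]


@dataclass(frozen=True)
class PopulationSpec:
    """Study conditions for the synthetic child population and closures."""

    total_children: int = 24_200_000
    race_counts: tuple[tuple[str, int], ...] = (
        ("White", 11_400_000),
        ("Hispanic", 4_300_000),
        ("Black", 3_600_000),
        ("Other", 4_900_000),
    )
    male_fraction: float = 0.512
    n_states: int = 51
    closure_median: float = 54.0
    closure_iqr: tuple[float, float] = (48.0, 62.5)
    closure_support: tuple[float, float] = (30.0, 85.0)
    attainment_mean: float = 13.7
    attainment_sd: float = 2.1
    state_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if sum(c for _, c in self.race_counts) > self.total_children:
            raise ValueError("race counts exceed total children")
        if not 0.0 < self.male_fraction < 1.0:
            raise ValueError("male_fraction must lie in (0, 1)")
        lo, hi = self.closure_iqr
        if not lo <= self.closure_median <= hi:
            raise ValueError("closure median must lie within the IQR")
        if self.state_weights is not None and len(self.state_weights) != self.n_states:
            raise ValueError("state_weights must have one entry per state")

    def weights(self) -> np.ndarray:
        if self.state_weights is not None:
            w = np.asarray(self.state_weights, dtype=float)
        else:
            w = np.array(list(STATE_WEIGHTS.values())[: self.n_states])
        return w / w.sum()

    def state_names(self) -> list[str]:
        names = list(STATE_WEIGHTS.keys())
        if self.n_states <= len(names):
            return names[: self.n_states]
        return names + [f"S{i}" for i in range(len(names), self.n_states)]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights, summing exactly to total."""
    shares = weights / weights.sum() * total
    base = np.floor(shares).astype(np.int64)
    short = total - int(base.sum())
    order = np.argsort(-(shares - base), kind="stable")
    base[order[:short]] += 1
    return base


@functools.lru_cache(maxsize=8)
def _closure_distribution(median: float, q1: float, q3: float, lo: float, hi: float):
    """Beta on [lo, hi] with shapes solved so quartiles hit (q1, median, q3)."""

    def resid(p):
        a, b = p
        return stats.beta.ppf([0.25, 0.5, 0.75], a, b, loc=lo, scale=hi - lo) - np.array(
            [q1, median, q3]
        )

    sol = least_squares(resid, x0=[2.0, 3.0], bounds=([0.2, 0.2], [100.0, 100.0]))
    a, b = sol.x
    return stats.beta(a, b, loc=lo, scale=hi - lo)


def generate_closure_days(spec: PopulationSpec, seed: int) -> pd.Series:
    """Per-state school-closure days (integer weekdays).

    Draws use randomized stratified inversion of the calibrated beta — one
    uniform per equal-probability stratum, assigned to states in random
    order — so that for *every* seed the 51-state sample median and IQR sit
    within a couple of days of the calibration targets, as they must for a
    quantity the downstream model is calibrated on.
    """
    rng = rng_for(seed, "closure-days")
    states = spec.state_names()
    n = len(states)
    q1, q3 = spec.closure_iqr
    if q1 == q3 == spec.closure_median:
        days = np.full(n, spec.closure_median)
    else:
        dist = _closure_distribution(
            spec.closure_median, q1, q3, spec.closure_support[0], spec.closure_support[1]
        )
        u = (np.arange(n) + rng.random(n)) / n
        days = dist.ppf(rng.permutation(u))
    return pd.Series(np.round(days).astype(int), index=pd.Index(states, name="state"))


def generate_population(spec: PopulationSpec, seed: int) -> ChildPopulation:
    """ACS-like child population plus closure days.

    Counts are allocated deterministically given the spec — race totals are
    exact by construction, states follow the share vector, sexes split by
    ``male_fraction`` and ages 5-11 uniformly — with largest-remainder
    rounding at every level so all totals match the spec exactly.
    """
    states = spec.state_names()
    w_state = spec.weights()
    sex_frac = {"male": spec.male_fraction, "female": 1.0 - spec.male_fraction}
    cell_w = np.array(
        [
            w_state[s] * sex_frac[sex] / len(CHILD_AGES)
            for s in range(len(states))
            for sex in ("male", "female")
            for _ in CHILD_AGES
        ]
    )
    rows = []
    for race, race_total in spec.race_counts:
        counts = _largest_remainder(cell_w, race_total)
        i = 0
        for s, state in enumerate(states):
            for sex in ("male", "female"):
                for age in CHILD_AGES:
                    rows.append((state, sex, race, age, counts[i]))
                    i += 1
    df = pd.DataFrame(rows, columns=["state", "sex", "race", "age", "count"])
    closure = generate_closure_days(spec, seed)
    return ChildPopulation(
        df, closure, attainment_baseline=(spec.attainment_mean, spec.attainment_sd)
    )


def builtin_death_table() -> DeathBandTable:
    """The bundled age-banded COVID-19 death table (11 bands x 2 sexes)."""
    df = pd.DataFrame(
        _DEATH_ROWS, columns=["midpoint_age", "sex", "deaths", "death_prob", "ex"]
    )
    return DeathBandTable(df[["midpoint_age", "sex", "deaths", "ex", "death_prob"]])


def builtin_expectancy_anchors() -> dict[str, ExpectancyAnchors]:
    """Per-sex remaining-life-expectancy anchors from the bundled table."""
    out = {}
    for sex in ("male", "female"):
        rows = [(a, e) for a, s, _, _, e in _DEATH_ROWS if s == sex]
        out[sex] = ExpectancyAnchors(
            sex=sex, ages=tuple(a for a, _ in rows), ex=tuple(e for _, e in rows)
        )
    return out


def default_life_tables(
    omega: int = 100,
    race_offsets: dict[str, float] | None = None,
    method: str = "hazard-interp",
) -> dict[tuple[str, str], LifeTable]:
    """Per-(sex, race) life tables reconstructed from the bundled anchors.

    ``race_offsets`` additively shifts the anchor expectancies per race
    (default: no shift, so every race shares the sex-average table, which is
    all the bundled anchors support).
    """
    race_offsets = race_offsets or {}
    anchors = builtin_expectancy_anchors()
    tables: dict[tuple[str, str], LifeTable] = {}
    for sex, anch in anchors.items():
        base = from_anchors(anch, omega=omega, method=method)
        tables[(sex, "All")] = base
        for race in ("White", "Black", "Hispanic", "Other"):
            off = race_offsets.get(race, 0.0)
            if off == 0.0:
                tables[(sex, race)] = base  # shared object: one survival cache
            else:
                shifted = ExpectancyAnchors(
                    sex=sex, ages=anch.ages, ex=tuple(e + off for e in anch.ex)
                )
                tables[(sex, race)] = from_anchors(
                    shifted, omega=omega, method=method, race=race
                )
    return tables
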