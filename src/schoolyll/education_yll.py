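"""Education-mediated years of life lost from missed primary-school days.

The causal chain is modeled in two stages:

1. *Closure -> attainment.* Missed school days reduce final educational
   attainment. The per-10-day coefficients (with standard errors) come from
   a quasi-experimental analysis of prolonged teacher strikes; draws are
   truncated-normal with a lower bound of zero (closures cannot raise
   attainment).
2. *Attainment -> mortality.* Each additional year of attained education
   multiplies annual mortality by a relative risk RR (default 0.75, 95% CI
   0.60-0.90, drawn plain normal). Losing ``L`` years therefore multiplies
   every annual death probability from the child's current age onward by
   ``RR**(-L)``, and the years of life lost are the resulting drop in
   (optionally discounted) remaining life expectancy.

Lifespan is capped at a terminal age of 85 by default — the model's maximum
age of death — which materially moderates how much a lifelong hazard
increase can shorten life.

Population totals share one relative-risk draw and one per-sex coefficient
draw across all population cells within a Monte Carlo iteration: the
uncertainty being propagated is parameter uncertainty, which is perfectly
correlated across children, not per-child sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import (
    SEXES,
    LifeTable,
    adjust_hazard,
    discounted_remaining_life,
)
from .mc_engine import TruncNormalParams, rng_for, sample_trunc_normal

__all__ = [
    "AttainmentEffect",
    "EducationMortalityEffect",
    "ChildPopulation",
    "MAX_AGE_OF_DEATH",
    "attainment_loss_draws",
    "sample_relative_risk",
    "hazard_multiplier",
    "per_child_yll",
    "per_child_yll_draws",
    "population_education_yll",
    "population_education_yll_multi",
]

#: Terminal age used for the education-mediated YLL arithmetic.
MAX_AGE_OF_DEATH = 85

CHILD_AGES = tuple(range(5, 12))


@dataclass(frozen=True)
class AttainmentEffect:
    """Years of final attainment lost per 10 missed school days, by sex."""

    male_coef: float = 0.0262
    male_se: float = 0.0064
    female_coef: float = 0.0217
    female_se: float = 0.0062

    def __post_init__(self) -> None:
        if self.male_coef < 0 or self.female_coef < 0:
            raise ValueError("attainment-loss coefficients must be >= 0")

    def for_sex(self, sex: str) -> TruncNormalParams:
        """Truncated-normal coefficient sampler (lower bound 0) for a sex."""
        if sex == "male":
            return TruncNormalParams(self.male_coef, self.male_se, lower=0.0)
        if sex == "female":
            return TruncNormalParams(self.female_coef, self.female_se, lower=0.0)
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")


@dataclass(frozen=True)
class EducationMortalityEffect:
    """Relative risk of annual mortality per additional year of education."""

    rr_mean: float = 0.75
    rr_ci: tuple[float, float] = (0.60, 0.90)

    def __post_init__(self) -> None:
        if not self.rr_mean > 0:
            raise ValueError("relative risk must be positive")
        if not self.rr_ci[0] <= self.rr_mean <= self.rr_ci[1]:
            raise ValueError("rr_mean must lie within rr_ci")

    @property
    def rr_sd(self) -> float:
        """SD from a symmetric-normal reading of the 95% CI: (hi - lo)/3.92."""
        return (self.rr_ci[1] - self.rr_ci[0]) / (2.0 * 1.959964)


class ChildPopulation:
    """Public-school children (state x sex x race x single-year age 5-11)
    together with per-state school-closure days.

    ``attainment_baseline`` is the (mean, sd) of final attainment among
    recent adults, carried as reporting metadata only: the model is a pure
    decrement model and never consumes the baseline level.
    """

    _COLUMNS = ["state", "sex", "race", "age", "count"]

    def __init__(
        self,
        df: pd.DataFrame,
        closure_days: pd.Series,
        attainment_baseline: tuple[float, float] | None = None,
    ):
        missing = [c for c in self._COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"population table missing columns {missing}")
        df = df[self._COLUMNS].copy()
        if not df["sex"].isin(SEXES).all():
            raise ValueError(f"sex must be one of {SEXES}")
        if not df["age"].isin(CHILD_AGES).all():
            raise ValueError("ages must lie in 5-11 inclusive")
        if (df["count"] < 0).any():
            raise ValueError("population counts must be non-negative")
        closure_days = pd.Series(closure_days, dtype=float)
        if (closure_days < 0).any():
            raise ValueError("closure days must be non-negative")
        unknown = set(df["state"]) - set(closure_days.index)
        if unknown:
            raise ValueError(f"states missing closure days: {sorted(unknown)[:5]}")
        self.df = df.reset_index(drop=True)
        self.closure_days = closure_days
        self.attainment_baseline = attainment_baseline

    def total_count(self) -> int:
        return int(self.df["count"].sum())

    @classmethod
    def from_csv(cls, population_path, closure_path) -> "ChildPopulation":
        pop = pd.read_csv(population_path)
        clo = pd.read_csv(closure_path)
        if list(clo.columns) != ["state", "closure_days"]:
            raise ValueError("closure CSV must have columns ['state', 'closure_days']")
        return cls(pop, clo.set_index("state")["closure_days"])

    def to_csv(self, population_path, closure_path) -> None:
        self.df.to_csv(population_path, index=False)
        self.closure_days.rename("closure_days").rename_axis("state").reset_index().to_csv(
            closure_path, index=False
        )


def attainment_loss_draws(
    days: float,
    sex: str,
    effect: AttainmentEffect,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draws of final attainment lost (years) after ``days`` missed days."""
    if days < 0:
        raise ValueError(f"missed days must be >= 0, got {days}")
    coef = sample_trunc_normal(effect.for_sex(sex), n, rng_for(seed))
    return (days / 10.0) * coef


def sample_relative_risk(
    effect: EducationMortalityEffect, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Plain-normal RR draws; non-positive draws (probability < 1e-21 at the
    defaults) are rejected and redrawn. Draws above 1 are retained — they
    yield small negative YLL and are part of the stated uncertainty."""
    rng = rng_for(seed)
    if effect.rr_sd == 0.0:
        return np.full(n, effect.rr_mean)
    rr = rng.normal(effect.rr_mean, effect.rr_sd, size=n)
    while (bad := rr <= 0).any():  # pragma: no cover - astronomically rare
        rr[bad] = rng.normal(effect.rr_mean, effect.rr_sd, size=int(bad.sum()))
    return rr


def hazard_multiplier(rr_draw, loss_years):
    """Multiplier on annual death probability: RR**(-loss). Vectorized."""
    rr_draw = np.asarray(rr_draw, dtype=float)
    if np.any(rr_draw <= 0):
        raise ValueError("relative risk draws must be positive")
    return rr_draw ** (-np.asarray(loss_years, dtype=float))


def per_child_yll(
    lt: LifeTable, age: int, multiplier: float, rate: float = 0.0
) -> float:
    """Discounted years of life a child at ``age`` loses when annual death
    probabilities from that age on are scaled by ``multiplier``.

    Non-negative whenever ``multiplier >= 1``; exactly 0 at multiplier 1.
    """
    if not 5 <= age <= 11:
        raise ValueError(f"child age must lie in 5-11, got {age}")
    base = discounted_remaining_life(lt, age, rate)
    adjusted = adjust_hazard(lt, multiplier, from_age=age)
    return base - discounted_remaining_life(adjusted, age, rate)


def _discount_weights(n_years: int, rates: np.ndarray) -> np.ndarray:
    """(n_years, n_rates) matrix of (1+r)^-t for t = 1..n_years."""
    t = np.arange(1, n_years + 1, dtype=float)
    return (1.0 + rates[None, :]) ** (-t[:, None])


def per_child_yll_draws(
    lt: LifeTable,
    age: int,
    days: float,
    sex: str,
    effect: AttainmentEffect,
    mort_effect: EducationMortalityEffect,
    n: int,
    seed: int,
    rate: float = 0.0,
    max_age_of_death: int = MAX_AGE_OF_DEATH,
) -> np.ndarray:
    """Monte Carlo YLL draws for a single child (vectorized over draws).

    Per draw, an attainment loss and an RR are sampled, combined into a
    hazard multiplier, and the drop in (discounted) remaining life
    expectancy on the capped table is recorded.
    """
    loss = attainment_loss_draws(days, sex, effect, n, rng_for(seed, f"attainment-{sex}"))
    rr = sample_relative_risk(mort_effect, n, rng_for(seed, "mortality-rr"))
    mult = hazard_multiplier(rr, loss)
    capped = lt.truncate(max_age_of_death) if lt.omega > max_age_of_death else lt
    qa = capped.qx[age:]
    weights = _discount_weights(qa.size, np.array([rate]))[:, 0]
    base = float(np.cumprod(1.0 - qa) @ weights) + 0.5
    out = np.empty(n)
    chunk = max(1, int(2_000_000 // max(qa.size, 1)))
    for i in range(0, n, chunk):
        m = mult[i : i + chunk]
        q_adj = np.minimum(1.0, m[:, None] * qa[None, :])
        surv = np.cumprod(1.0 - q_adj, axis=1)
        out[i : i + chunk] = base - (surv @ weights + 0.5)
    return out


def population_education_yll(
    pop: ChildPopulation,
    effect: AttainmentEffect,
    mort_effect: EducationMortalityEffect,
    tables: dict[tuple[str, str], LifeTable],
    rate: float,
    n: int,
    seed: int,
    max_age_of_death: int = MAX_AGE_OF_DEATH,
    rr_from_age: str = "child",
) -> np.ndarray:
    """Draws of total education-mediated YLL (person-years) at one rate."""
    return population_education_yll_multi(
        pop, effect, mort_effect, tables, [rate], n, seed,
        max_age_of_death=max_age_of_death, rr_from_age=rr_from_age,
    )[:, 0]


def population_education_yll_multi(
    pop: ChildPopulation,
    effect: AttainmentEffect,
    mort_effect: EducationMortalityEffect,
    tables: dict[tuple[str, str], LifeTable],
    rates,
    n: int,
    seed: int,
    max_age_of_death: int = MAX_AGE_OF_DEATH,
    rr_from_age: str = "child",
    chunk: int = 512,
) -> np.ndarray:
    """Population education-YLL draws for several discount rates at once.

    The survival computation is the cost driver and is independent of the
    discount rate, so all rates share each draw's adjusted survival curves.
    Returns an (n, len(rates)) array in person-years. ``rr_from_age``
    selects whether the hazard multiplier applies from the child's current
    age (default) or only from adulthood (``"adult"``, age 18).
    """
    if rr_from_age not in ("child", "adult"):
        raise ValueError(f"rr_from_age must be 'child' or 'adult', got {rr_from_age!r}")
    rates = np.asarray(list(rates), dtype=float)
    if (rates < 0).any():
        raise ValueError("discount rates must be >= 0")
    out = np.zeros((n, rates.size))
    if len(pop.df) == 0:
        return out

    rr = sample_relative_risk(mort_effect, n, rng_for(seed, "mortality-rr"))
    neg_log_rr = -np.log(rr)
    coef = {
        sex: sample_trunc_normal(effect.for_sex(sex), n, rng_for(seed, f"attainment-{sex}"))
        for sex in SEXES
    }

    def resolve(sex: str, race: str) -> LifeTable:
        lt = tables.get((sex, race)) or tables.get((sex, "All"))
        if lt is None:
            raise KeyError(f"no life table configured for stratum ({sex}, {race})")
        return lt

    # group population cells by the table object actually backing them
    groups: dict[tuple[str, int], tuple[LifeTable, list[int]]] = {}
    for idx, row in enumerate(pop.df.itertuples()):
        lt = resolve(row.sex, row.race)
        key = (row.sex, id(lt))
        groups.setdefault(key, (lt, []))[1].append(idx)

    for (sex, _), (lt, idxs) in groups.items():
        sub = pop.df.iloc[idxs]
        cells = sub.groupby(["state", "age"], sort=True)["count"].sum().unstack(fill_value=0.0)
        states = cells.index.to_numpy()
        days = pop.closure_days.loc[states].to_numpy(dtype=float)
        capped = lt.truncate(max_age_of_death) if lt.omega > max_age_of_death else lt

        for age in cells.columns:
            w = cells[age].to_numpy(dtype=float)  # per-state counts at this age
            if not w.any():
                continue
            qa = capped.qx[int(age):]
            disc = _discount_weights(qa.size, rates)  # (L, R)
            base = np.cumprod(1.0 - qa) @ disc + 0.5  # (R,)
            start = 0 if rr_from_age == "child" else max(0, 18 - int(age))
            for i in range(0, n, chunk):
                sl = slice(i, min(i + chunk, n))
                loss = np.outer(days / 10.0, coef[sex][sl])          # (S, c)
                mult = np.exp(loss * neg_log_rr[sl][None, :])        # (S, c)
                q_adj = np.broadcast_to(qa, (len(days), loss.shape[1], qa.size)).copy()
                q_adj[:, :, start:] = np.minimum(
                    1.0, mult[:, :, None] * qa[None, None, start:]
                )
                surv = np.cumprod(1.0 - q_adj, axis=2)               # (S, c, L)
                e_adj = surv @ disc + 0.5                            # (S, c, R)
                delta = base[None, None, :] - e_adj
                out[sl] += np.einsum("s,scr->cr", w, delta)
    return out
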