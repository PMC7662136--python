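"""Years of life lost directly attributable to COVID-19 deaths.

Deaths are tabulated in 10-year age bands per sex; each band carries a
midpoint age and the remaining life expectancy at that midpoint, so the
direct burden is simply ``sum(deaths * e(midpoint))``. Reported death
counts are a known undercount, corrected by a multiplicative PERT-drawn
ratio (minimum 1: excess deaths are assumed non-negative).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .life_tables import SEXES, LifeTable, remaining_life
from .mc_engine import PertParams, rng_for, sample_pert

__all__ = [
    "DeathBandTable",
    "DEFAULT_UNDERCOUNT",
    "yll_from_deaths",
    "total_deaths",
    "corrected_direct_yll",
]

#: Reported-death undercount ratio: minimum 1, modal 1.22 (excess-mortality
#: comparison for New York state, early 2020), maximum = doubled mode.
DEFAULT_UNDERCOUNT = PertParams(1.0, 1.22, 2.44)

_REQUIRED = ["midpoint_age", "sex", "deaths"]
_OPTIONAL = ["ex", "death_prob"]


class DeathBandTable:
    """Age-banded COVID-19 death counts per sex, with band life expectancies.

    Columns: ``midpoint_age`` (years, band midpoint, max 85), ``sex``,
    ``deaths`` (count), optional ``ex`` (remaining life expectancy at the
    midpoint) and ``death_prob`` (annual death probability; carried and
    validated for completeness but not used in any YLL arithmetic).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"death-band table missing columns {missing}")
        extra = [c for c in df.columns if c not in _REQUIRED + _OPTIONAL]
        if extra:
            raise ValueError(f"unexpected death-band columns {extra}")
        df = df.copy()
        df["deaths"] = df["deaths"].astype(int)
        if (df["deaths"] < 0).any():
            raise ValueError("death counts must be non-negative")
        if not df["sex"].isin(SEXES).all():
            raise ValueError(f"sex must be one of {SEXES}")
        if (df["midpoint_age"] > 85).any():
            raise ValueError("band midpoints may not exceed 85 (maximum age of death)")
        if "ex" in df.columns and (df["ex"].dropna() <= 0).any():
            raise ValueError("band life expectancies must be positive")
        if "death_prob" in df.columns:
            dp = df["death_prob"].dropna()
            if ((dp < 0) | (dp > 1)).any():
                raise ValueError("death probabilities must lie in [0, 1]")
        for _, grp in df.groupby("sex"):
            if (np.diff(grp["midpoint_age"].to_numpy()) <= 0).any():
                raise ValueError("band midpoints must be strictly increasing per sex")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(cls, path) -> "DeathBandTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def total_deaths(table: DeathBandTable) -> int:
    """Total reported deaths across all bands and sexes."""
    return int(table.df["deaths"].sum())


def yll_from_deaths(
    table: DeathBandTable, tables: dict[str, LifeTable] | None = None
) -> tuple[float, pd.DataFrame]:
    """Direct YLL: per-row ``deaths * e(midpoint)`` and the grand total.

    Band expectancies come from the table's own ``ex`` column; rows lacking
    it fall back to ``e(midpoint)`` of a supplied per-sex life table.
    Returns ``(total_person_years, per_row_frame)`` where the frame carries
    an added ``yll`` column.
    """
    df = table.df.copy()
    if "ex" not in df.columns:
        df["ex"] = np.nan
    need = df["ex"].isna()
    if need.any():
        if tables is None:
            raise ValueError(
                "rows lack band life expectancy; supply per-sex life tables"
            )
        df.loc[need, "ex"] = [
            remaining_life(tables[row.sex], int(round(row.midpoint_age)))
            for row in df.loc[need].itertuples()
        ]
    df["yll"] = df["deaths"] * df["ex"]
    return float(df["yll"].sum()), df


def corrected_direct_yll(
    base_yll: float,
    n: int,
    seed: int | np.random.Generator,
    undercount: PertParams = DEFAULT_UNDERCOUNT,
) -> np.ndarray:
    """Undercount-corrected direct YLL draws: ``base_yll`` x PERT ratio."""
    if base_yll < 0:
        raise ValueError(f"base YLL must be non-negative, got {base_yll}")
    ratio = sample_pert(undercount, n, rng_for(seed))
    return base_yll * ratio
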