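"""Model configuration: every sampled or fixed parameter in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .education_yll import MAX_AGE_OF_DEATH, AttainmentEffect, EducationMortalityEffect
from .mc_engine import PertParams
from .synthetic_data import PopulationSpec

__all__ = ["ModelParams", "DEFAULT_MORTALITY_RATIO"]

#: Counterfactual schools-open mortality ratio: minimum 1 (children do not
#: measurably spread disease), maximum 2.85 (published closure-effect
#: estimate), mode 1.93 (average of the two published estimates).
DEFAULT_MORTALITY_RATIO = PertParams(1.0, 1.93, 2.85)


@dataclass(frozen=True)
class ModelParams:
    """All tunables of the closed-versus-open comparison.

    Attributes
    ----------
    attainment, mortality
        Stage-1 and stage-2 education-effect parameters.
    undercount, mortality_ratio
        PERT triples for the death-undercount correction and the
        counterfactual schools-open mortality ratio.
    discount_rates
        Annual rates applied to education-mediated (future) life-years;
        direct YLL is never discounted (those deaths occurred in 2020).
    max_age_of_death
        Terminal age of the YLL arithmetic (default 85).
    rr_from_age
        ``"child"``: the education hazard multiplier applies from the
        child's current age on; ``"adult"``: only from age 18.
    paired
        Share the direct-YLL draws between the closed and open scenario
        within each iteration (paired comparison). ``False`` draws an
        independent undercount stream for the open branch.
    """

    attainment: AttainmentEffect = field(default_factory=AttainmentEffect)
    mortality: EducationMortalityEffect = field(default_factory=EducationMortalityEffect)
    undercount: PertParams = PertParams(1.0, 1.22, 2.44)
    mortality_ratio: PertParams = DEFAULT_MORTALITY_RATIO
    discount_rates: tuple[float, ...] = (0.0, 0.005, 0.03)
    n_draws: int = 100_000
    seed: int = 0
    ci_level: float = 0.95
    max_age_of_death: int = MAX_AGE_OF_DEATH
    rr_from_age: str = "child"
    paired: bool = True
    population: PopulationSpec = field(default_factory=PopulationSpec)

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if any(r < 0 for r in self.discount_rates):
            raise ValueError("discount rates must be >= 0")

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        """Load from YAML or JSON; keys mirror the dataclass fields."""
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelParams":
        kwargs = dict(raw)
        for key, typ in (
            ("attainment", AttainmentEffect),
            ("mortality", EducationMortalityEffect),
            ("population", PopulationSpec),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = kwargs[key]
                if key == "mortality" and "rr_ci" in sub:
                    sub["rr_ci"] = tuple(sub["rr_ci"])
                if key == "population":
                    if "race_counts" in sub:
                        sub["race_counts"] = tuple(
                            (r, int(c)) for r, c in dict(sub["race_counts"]).items()
                        )
                    for k in ("closure_iqr", "closure_support", "state_weights"):
                        if sub.get(k) is not None:
                            sub[k] = tuple(sub[k])
                kwargs[key] = typ(**sub)
        for key in ("undercount", "mortality_ratio"):
            if key in kwargs and isinstance(kwargs[key], (list, tuple)):
                kwargs[key] = PertParams(*kwargs[key])
        if "discount_rates" in kwargs:
            kwargs["discount_rates"] = tuple(kwargs["discount_rates"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)
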