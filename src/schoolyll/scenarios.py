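"""Scenario assembly: closed versus open schools, compared draw by draw.

*Closed* (what happened): undercount-corrected direct YLL from COVID-19
deaths plus education-mediated YLL from missed instruction.

*Open* (counterfactual): the same corrected direct YLL scaled by a
PERT-drawn schools-open mortality ratio; no education loss.

Within each Monte Carlo iteration the two scenarios share the direct-YLL
draw (a paired comparison), so the exceedance probability
``P(direct + education > direct * ratio)`` is algebraically identical to
``P(education > direct * (ratio - 1))``. Direct YLL is never discounted
(those deaths occurred in 2020); only the education component, which plays
out over the children's lifetimes, responds to the discount rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .direct_yll import corrected_direct_yll, total_deaths, yll_from_deaths
from .education_yll import population_education_yll_multi
from .mc_engine import (
    DrawSummary,
    PertParams,
    prob_greater,
    rng_for,
    sample_pert,
    summarize_draws,
)
from .params import DEFAULT_MORTALITY_RATIO, ModelParams
from .synthetic_data import (
    builtin_death_table,
    default_life_tables,
    generate_population,
)

__all__ = [
    "ScenarioDraws",
    "ScenarioComparison",
    "ModelReport",
    "open_scenario_yll",
    "compare_scenarios",
    "run_full_model",
]


@dataclass(frozen=True)
class ScenarioDraws:
    """Per-draw YLL vectors for both scenarios (person-years)."""

    closed_direct: np.ndarray
    education: dict[float, np.ndarray]  # keyed by discount rate
    open_total: np.ndarray
    mortality_ratio_params: PertParams = DEFAULT_MORTALITY_RATIO

    def __post_init__(self) -> None:
        n = self.closed_direct.size
        sizes = {v.size for v in self.education.values()} | {self.open_total.size}
        if sizes != {n}:
            raise ValueError("all draw vectors must have equal length")


@dataclass(frozen=True)
class ScenarioComparison:
    """Exceedance probability plus summaries of both scenario totals."""

    prob_closed_exceeds_open: float
    closed_summary: DrawSummary
    open_summary: DrawSummary


def open_scenario_yll(
    closed_direct: np.ndarray,
    seed: int | np.random.Generator,
    ratio: PertParams = DEFAULT_MORTALITY_RATIO,
) -> np.ndarray:
    """Counterfactual draws: direct YLL scaled by fresh mortality-ratio draws."""
    closed_direct = np.asarray(closed_direct, dtype=float)
    r = sample_pert(ratio, closed_direct.size, rng_for(seed))
    return closed_direct * r


def compare_scenarios(
    closed_direct: np.ndarray,
    education: np.ndarray,
    open_total: np.ndarray,
    level: float = 0.95,
) -> ScenarioComparison:
    """Paired comparison of total YLL under closure versus reopening."""
    closed_total = np.asarray(closed_direct) + np.asarray(education)
    prob = prob_greater(closed_total, open_total)
    return ScenarioComparison(
        prob_closed_exceeds_open=prob,
        closed_summary=summarize_draws(closed_total, level),
        open_summary=summarize_draws(open_total, level),
    )


@dataclass(frozen=True)
class ModelReport:
    """Everything the full model computes, plus serialization helpers."""

    params: ModelParams
    draws: ScenarioDraws
    base_direct_yll: float
    reported_deaths: int
    direct_summary: DrawSummary
    open_summary: DrawSummary
    incremental_open_summary: DrawSummary
    education_summaries: dict[float, DrawSummary]
    exceedance: dict[float, float]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-quantity summary table (person-years / probabilities)."""
        rows = [
            ("corrected_direct_yll", None, self.direct_summary),
            ("open_scenario_yll", None, self.open_summary),
            ("incremental_open_yll", None, self.incremental_open_summary),
        ]
        rows += [
            ("education_yll", rate, s) for rate, s in self.education_summaries.items()
        ]
        recs = [
            {
                "quantity": name,
                "discount_rate": rate,
                "median": s.median,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "level": s.level,
            }
            for name, rate, s in rows
        ]
        recs += [
            {
                "quantity": "prob_closed_exceeds_open",
                "discount_rate": rate,
                "median": p,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "level": np.nan,
            }
            for rate, p in self.exceedance.items()
        ]
        return pd.DataFrame.from_records(recs)

    def to_dict(self) -> dict:
        def s(d: DrawSummary) -> dict:
            return {
                "median": round(float(d.median), 6),
                "ci_low": float(d.ci_low),
                "ci_high": float(d.ci_high),
                "level": d.level,
            }

        return {
            "reported_deaths": self.reported_deaths,
            "base_direct_yll": self.base_direct_yll,
            "n_draws": self.params.n_draws,
            "seed": self.params.seed,
            "corrected_direct_yll": s(self.direct_summary),
            "open_scenario_yll": s(self.open_summary),
            "incremental_open_yll": s(self.incremental_open_summary),
            "education_yll": {str(r): s(d) for r, d in self.education_summaries.items()},
            "prob_closed_exceeds_open": {
                str(r): round(p, 3) for r, p in self.exceedance.items()
            },
        }

    def save(self, out_dir, plot: bool = False) -> None:
        """Write summary.csv + report.json (and optionally densities.png)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "summary.csv", index=False)
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        if plot:
            self.plot_densities(out / "densities.png")

    def plot_densities(self, path=None):
        """Density summaries of both scenarios per discount rate."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde

        fig, ax = plt.subplots(figsize=(8, 4.5))
        series = {"schools open (counterfactual)": self.draws.open_total}
        for rate, edu in self.draws.education.items():
            label = f"schools closed, {rate:.1%} discount"
            series[label] = self.draws.closed_direct + edu
        grid = np.linspace(0, max(v.max() for v in series.values()), 400)
        for label, v in series.items():
            kde = gaussian_kde(v / 1e6)
            ax.plot(grid / 1e6, kde(grid / 1e6), label=label)
        ax.set_xlabel("total years of life lost (millions)")
        ax.set_ylabel("probability density")
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return ax


def run_full_model(config: ModelParams | str | Path | None = None) -> ModelReport:
    """End-to-end run of the closed-versus-open comparison.

    Builds (or loads, when the config is a file path) the model inputs,
    propagates all parameter uncertainty through both scenarios with
    per-parameter seed substreams, and returns a :class:`ModelReport` with
    per-discount-rate summaries and exceedance probabilities.
    """
    if config is None:
        params = ModelParams()
    elif isinstance(config, (str, Path)):
        params = ModelParams.from_file(config)
    else:
        params = config
    n, seed = params.n_draws, params.seed

    try:
        tables = default_life_tables()
        pop = generate_population(params.population, seed)
        deaths = builtin_death_table()
        base_yll, _ = yll_from_deaths(deaths)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"input-assembly stage failed: {exc}") from exc

    closed_direct = corrected_direct_yll(
        base_yll, n, rng_for(seed, "undercount"), undercount=params.undercount
    )
    direct_for_open = closed_direct
    if not params.paired:
        direct_for_open = corrected_direct_yll(
            base_yll, n, rng_for(seed, "undercount-open"), undercount=params.undercount
        )
    open_total = open_scenario_yll(
        direct_for_open, rng_for(seed, "mortality-ratio"), ratio=params.mortality_ratio
    )

    try:
        edu = population_education_yll_multi(
            pop,
            params.attainment,
            params.mortality,
            tables,
            params.discount_rates,
            n,
            seed,
            max_age_of_death=params.max_age_of_death,
            rr_from_age=params.rr_from_age,
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"education-YLL stage failed: {exc}") from exc

    education = {rate: edu[:, i] for i, rate in enumerate(params.discount_rates)}
    draws = ScenarioDraws(
        closed_direct=closed_direct,
        education=education,
        open_total=open_total,
        mortality_ratio_params=params.mortality_ratio,
    )
    level = params.ci_level
    return ModelReport(
        params=params,
        draws=draws,
        base_direct_yll=base_yll,
        reported_deaths=total_deaths(deaths),
        direct_summary=summarize_draws(closed_direct, level),
        open_summary=summarize_draws(open_total, level),
        incremental_open_summary=summarize_draws(open_total - closed_direct, level),
        education_summaries={
            rate: summarize_draws(v, level) for rate, v in education.items()
        },
        exceedance={
            rate: prob_greater(closed_direct + v, open_total)
            for rate, v in education.items()
        },
    )
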