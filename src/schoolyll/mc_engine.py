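"""Seeded sampling primitives and Monte Carlo draw summaries.

All stochastic stages of the model draw from the two elicitation-friendly
families used throughout health decision analysis:

* the PERT distribution — a rescaled beta parameterized by the minimum,
  most-likely (modal) and maximum value of a quantity, weighting the mode
  roughly four-fold relative to the extremes; and
* the (optionally truncated) normal, for regression coefficients reported
  with a standard error.

A single master seed spawns independent substreams per named parameter, so
enlarging the draw count of one parameter never perturbs the draw sequence
of another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PertParams",
    "TruncNormalParams",
    "DrawSummary",
    "rng_for",
    "sample_pert",
    "sample_trunc_normal",
    "summarize_draws",
    "prob_greater",
]


def rng_for(seed: int | np.random.Generator, label: str | None = None) -> np.random.Generator:
    """Return a Generator for ``seed``; with ``label``, an independent substream.

    Substreams are derived from ``SeedSequence(seed, spawn_key=(crc32(label),))``
    so that streams for distinct parameter names are statistically independent
    yet fully reproducible from the single master seed.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if label is None:
        return np.random.default_rng(seed)
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class PertParams:
    """Three-point (min, mode, max) specification of a PERT distribution.

    ``shape`` is the modal weight of the classic PERT (default 4); the
    implied beta shapes on [0, 1] are ``alpha = 1 + shape*(mode-min)/range``
    and ``beta = 1 + shape*(max-mode)/range``.
    """

    minimum: float
    mode: float
    maximum: float
    shape: float = 4.0

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mode <= self.maximum):
            raise ValueError(
                f"PERT triple must satisfy min <= mode <= max, got "
                f"({self.minimum}, {self.mode}, {self.maximum})"
            )
        if not self.shape > 0:
            raise ValueError(f"PERT shape must be positive, got {self.shape}")

    @property
    def mean(self) -> float:
        """Closed-form mean (min + shape*mode + max) / (shape + 2)."""
        return (self.minimum + self.shape * self.mode + self.maximum) / (self.shape + 2.0)

    @property
    def beta_shapes(self) -> tuple[float, float]:
        span = self.maximum - self.minimum
        if span == 0.0:
            raise ValueError("degenerate PERT (min == max) has no beta representation")
        alpha = 1.0 + self.shape * (self.mode - self.minimum) / span
        beta = 1.0 + self.shape * (self.maximum - self.mode) / span
        return alpha, beta


@dataclass(frozen=True)
class TruncNormalParams:
    """Normal(mean, sd) restricted to [lower, upper]; infinite bounds allowed."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if not self.lower < self.upper:
            raise ValueError(f"require lower < upper, got [{self.lower}, {self.upper}]")


@dataclass(frozen=True)
class DrawSummary:
    """Median and equal-tailed credible interval of a draw vector."""

    median: float
    ci_low: float
    ci_high: float
    level: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("summary must satisfy ci_low <= median <= ci_high")


def sample_pert(
    params: PertParams, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` PERT variates; the degenerate triple returns a point mass."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = rng_for(seed)
    if params.maximum == params.minimum:
        return np.full(n, float(params.mode))
    alpha, beta = params.beta_shapes
    u = rng.beta(alpha, beta, size=n)
    return params.minimum + (params.maximum - params.minimum) * u


def sample_trunc_normal(
    params: TruncNormalParams, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` truncated-normal variates; sd = 0 gives a point mass at the mean."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = rng_for(seed)
    if params.sd == 0.0:
        if not (params.lower <= params.mean <= params.upper):
            raise ValueError(
                f"degenerate (sd=0) mean {params.mean} lies outside "
                f"[{params.lower}, {params.upper}]"
            )
        return np.full(n, float(params.mean))
    a = (params.lower - params.mean) / params.sd
    b = (params.upper - params.mean) / params.sd
    return stats.truncnorm.rvs(
        a, b, loc=params.mean, scale=params.sd, size=n, random_state=rng
    )


def summarize_draws(draws: np.ndarray, level: float = 0.95) -> DrawSummary:
    """Median plus equal-tailed percentile interval at the given level."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarize an empty draw vector")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(draws, [tail, 0.5, 1.0 - tail])
    return DrawSummary(median=float(med), ci_low=float(lo), ci_high=float(hi), level=level)


def prob_greater(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of paired draws with ``a_i > b_i`` (strict inequality)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired draws need equal shapes, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("cannot compare empty draw vectors")
    return float(np.mean(a > b))
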