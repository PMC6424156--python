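"""Last-survivor exceedance: how long should the record holder live?

Given ``N`` individuals alive at a plateau entry age, each with annual
survival ``p``, the probability that *anybody* in the group is still alive
``t`` years later is the exceedance probability of the cohort maximum,

    P(t, N) = 1 - (1 - p**t) ** N.

This module evaluates that closed form in a numerically stable way and
cross-checks it by direct Monte Carlo simulation of cohorts of residual
lifespans, with a Wilson binomial confidence interval on the simulated
fraction (exceedance probabilities of interest here are close to 0, where
the Wald interval misbehaves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .hazards import HazardModel

__all__ = [
    "PlausibilityResult",
    "last_survivor_exceedance",
    "estimate_exceedance_mc",
    "max_survivor_quantiles",
]

# cap on lifespans drawn per chunk, keeps the MC loop at ~tens of MB
_CHUNK_DRAWS = 4_000_000


def last_survivor_exceedance(t, N: int, p: float) -> float:
    """Closed-form P(t, N) = 1 - (1 - p**t)**N.

    Evaluated as ``-expm1(N * log1p(-p**t))`` so that tiny ``p**t`` and very
    large ``N`` (up to ~1e9) lose no precision: for ``N·p**t << 1`` the
    result agrees with the first-order expansion ``N·p**t``.
    """
    N = int(N)
    if N < 1:
        raise ValueError(f"cohort size N must be >= 1, got {N}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"annual survival p must be in (0, 1), got {p}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("threshold t must be >= 0")
    with np.errstate(divide="ignore"):
        log_one_dead = np.log1p(-np.exp(t * math.log(p)))  # log(1 - p^t)
        out = -np.expm1(N * log_one_dead)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PlausibilityResult:
    """Analytic and Monte Carlo exceedance probability for one (t, N, p)."""

    t: float
    N: int
    annual_survival_p: float
    analytic_prob: float
    mc_estimate: Optional[float] = None
    mc_ci: Optional[Tuple[float, float]] = None
    reps: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.analytic_prob <= 1.0:
            raise ValueError("analytic_prob must be a probability")
        if self.mc_estimate is not None and self.mc_ci is not None:
            lo, hi = self.mc_ci
            if not lo - 1e-12 <= self.mc_estimate <= hi + 1e-12:
                raise ValueError("mc_ci must contain mc_estimate")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["mc_ci"] is not None:
            d["mc_ci"] = list(d["mc_ci"])
        return d


def _simulate_max_hits(N, model, reps, rng, threshold=None, collect=False):
    """Stream cohorts of size N; count maxima >= threshold and/or collect maxima."""
    rows_per_chunk = max(1, _CHUNK_DRAWS // N)
    hits = 0
    maxima = [] if collect else None
    done = 0
    while done < reps:
        rows = min(rows_per_chunk, reps - done)
        draws = model.sample_lifespans(rows * N, rng=rng).reshape(rows, N)
        m = draws.max(axis=1)
        if threshold is not None:
            hits += int(np.count_nonzero(m >= threshold))
        if collect:
            maxima.append(m)
        done += rows
    return hits, (np.concatenate(maxima) if collect else None)


def estimate_exceedance_mc(
    t: float,
    N: int,
    model: HazardModel,
    reps: int = 100_000,
    seed=None,
    alpha: float = 0.05,
) -> PlausibilityResult:
    """Monte Carlo estimate of P(max residual lifespan in a cohort of N >= t).

    Simulates ``reps`` cohorts of ``N`` residual lifespans from ``model`` and
    reports the fraction of cohorts whose longest-lived member reaches ``t``,
    with a Wilson score interval at level ``1 - alpha``.  The analytic
    probability ``1 - (1 - S(t))**N`` is attached for comparison.
    """
    reps = int(reps)
    if reps < 100:
        raise ValueError(f"reps must be >= 100 for a meaningful CI, got {reps}")
    N = int(N)
    if N < 1:
        raise ValueError(f"cohort size N must be >= 1, got {N}")
    if t < 0:
        raise ValueError("threshold t must be >= 0")

    rng = np.random.default_rng(seed)
    hits, _ = _simulate_max_hits(N, model, reps, rng, threshold=t)
    est = hits / reps
    lo, hi = proportion_confint(hits, reps, alpha=alpha, method="wilson")

    s_t = float(model.survival(t))
    with np.errstate(divide="ignore"):
        analytic = float(-np.expm1(N * np.log1p(-s_t)))
    return PlausibilityResult(
        t=float(t),
        N=N,
        annual_survival_p=float(model.survival(1.0)),
        analytic_prob=analytic,
        mc_estimate=est,
        mc_ci=(float(lo), float(hi)),
        reps=reps,
        seed=seed,
    )


def max_survivor_quantiles(
    N: int,
    model: HazardModel,
    reps: int = 100_000,
    seed=None,
    quantiles: Sequence[float] = (0.5,),
) -> np.ndarray:
    """Empirical quantiles (years) of the longest residual lifespan in a cohort.

    Summarises how far beyond the entry age the record holder of a size-``N``
    group typically gets under ``model``.
    """
    reps = int(reps)
    if reps < 100:
        raise ValueError(f"reps must be >= 100, got {reps}")
    q = np.asarray(list(quantiles), dtype=float)
    if q.size == 0:
        raise ValueError("quantile list must not be empty")
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantiles must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    _, maxima = _simulate_max_hits(int(N), model, reps, rng, collect=True)
    return np.quantile(maxima, q)
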