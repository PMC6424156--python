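"""Parametric mortality laws for extreme-age survival analysis.

Two families are provided:

* :class:`ConstantHazard` — the mortality *plateau* assumption: beyond some
  entry age (say 110) the force of mortality is flat, so the annual survival
  probability ``p`` is age-invariant and residual lifespans are exponential
  with rate ``-ln(p)`` per year.  ``p = 0.5`` ("half of the survivors die
  each year") is the conventional plateau value for supercentenarians.
* :class:`GompertzMakehamHazard` — the contrast model in which the force of
  mortality rises exponentially with age, ``h(x) = c + a·exp(b·x)``, with an
  optional age-independent (Makeham) component ``c`` capturing background
  mortality that does not grow with age.  With ``c = 0`` it is the pure
  Gompertz law.

Time is measured in years throughout and residual lifespans are continuous
(no discretisation to whole years).  Every stochastic operation takes an
explicit seed or a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HazardModel",
    "ConstantHazard",
    "GompertzMakehamHazard",
    "survival_beyond",
    "sample_lifespans",
]


def _as_rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


class HazardModel(abc.ABC):
    """A parametric mortality law conditioned on survival to ``entry_age``.

    ``survival(t)`` is the probability that the *residual* lifespan beyond
    the entry age exceeds ``t`` years; ``hazard(age)`` is the force of
    mortality (deaths per person-year) at an absolute age.
    """

    entry_age: float

    @abc.abstractmethod
    def hazard(self, age):
        """Force of mortality at absolute ``age`` (per year)."""

    @abc.abstractmethod
    def survival(self, t):
        """P(residual lifespan beyond ``entry_age`` > ``t``); ``t >= 0``."""

    @abc.abstractmethod
    def _sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ...

    def sample_lifespans(self, n: int, seed=None, rng=None) -> np.ndarray:
        """Draw ``n`` i.i.d. residual lifespans (years beyond entry age).

        Sampling is by inverse-CDF (plus competing risks for the Makeham
        component), so the draws follow the model's closed-form survival
        function exactly.
        """
        n = int(n)
        if n < 1:
            raise ValueError(f"need at least one draw, got n={n}")
        return self._sample(n, _as_rng(seed, rng))

    @staticmethod
    def _check_t(t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("residual time t must be >= 0")
        return t


@dataclass(frozen=True)
class ConstantHazard(HazardModel):
    """Constant force of mortality parameterised by annual survival ``p``.

    The hazard rate is ``mu = -ln(p)`` per year and residual lifespans are
    exponential: ``S(t) = p**t``.
    """

    annual_survival_p: float = 0.5
    entry_age: float = 0.0

    def __post_init__(self):
        p = self.annual_survival_p
        if not 0.0 < p < 1.0:
            raise ValueError(f"annual survival p must be in (0, 1), got {p}")

    @property
    def rate(self) -> float:
        """Hazard rate mu = -ln(p), deaths per person-year."""
        return -math.log(self.annual_survival_p)

    def hazard(self, age):
        return np.broadcast_to(self.rate, np.shape(age)).astype(float) if np.ndim(age) else self.rate

    def survival(self, t):
        t = self._check_t(t)
        out = np.exp(t * math.log(self.annual_survival_p))
        return float(out) if out.ndim == 0 else out

    def _sample(self, n, rng):
        return rng.exponential(scale=1.0 / self.rate, size=n)


@dataclass(frozen=True)
class GompertzMakehamHazard(HazardModel):
    """Gompertz–Makeham law ``h(x) = c + a·exp(b·x)`` at absolute age ``x``.

    Parameters
    ----------
    a : baseline Gompertz hazard at age 0 (per year, > 0).
    b : exponential slope of log-hazard with age (per year, > 0).
    c : Makeham age-independent hazard (per year, >= 0); 0 gives pure Gompertz.
    entry_age : age (years) survival is conditioned on.

    Residual survival beyond the entry age ``x0`` has the closed form
    ``S(t) = exp(-c·t - (a/b)·exp(b·x0)·(exp(b·t) - 1))``.
    """

    a: float = 1e-5
    b: float = 0.1
    c: float = 0.0
    entry_age: float = 0.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Gompertz parameters a and b must be > 0")
        if self.c < 0:
            raise ValueError("Makeham parameter c must be >= 0")

    def hazard(self, age):
        age = np.asarray(age, dtype=float)
        out = self.c + self.a * np.exp(self.b * age)
        return float(out) if out.ndim == 0 else out

    def survival(self, t):
        t = self._check_t(t)
        a_eff = self.a * math.exp(self.b * self.entry_age)
        with np.errstate(over="ignore"):  # overflow -> survival 0, the right limit
            out = np.exp(-self.c * t - (a_eff / self.b) * np.expm1(self.b * t))
        return float(out) if out.ndim == 0 else out

    def _sample(self, n, rng):
        # Gompertz part by exact inverse CDF conditioned on the entry age.
        a_eff = self.a * math.exp(self.b * self.entry_age)
        u = rng.random(n)
        t = np.log1p(-(self.b / a_eff) * np.log(u)) / self.b
        if self.c > 0:
            # Makeham component as a competing exponential risk: the total
            # hazard is the sum, so the residual lifespan is the minimum.
            t = np.minimum(t, rng.exponential(scale=1.0 / self.c, size=n))
        return t


def survival_beyond(model: HazardModel, t):
    """Probability that the residual lifespan exceeds ``t`` years."""
    return model.survival(t)


def sample_lifespans(model: HazardModel, n: int, seed=None, rng=None) -> np.ndarray:
    """Draw ``n`` residual lifespans from ``model`` (see the method docs)."""
    return model.sample_lifespans(n, seed=seed, rng=rng)
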