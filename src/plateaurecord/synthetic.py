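"""Synthetic datasets emulating the study's real inputs.

The real inputs — a validated supercentenarian register (entry at age 110,
roughly exponential residual lifespans with annual survival about 0.5),
small multi-generation ancestor cohorts whose groups differ in early-adult
(background) mortality rather than in old-age longevity, and national
period life tables — are not redistributable, so every pipeline input is
generated here instead.  Identical generator settings and seed produce
byte-identical CSV output.

Lifespans are drawn from the hazard models in :mod:`plateaurecord.hazards`;
calendar dates are uniform in a window and matter only for the exact-date
arithmetic (none of the downstream statistics depends on the date
distribution).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohorts import DAYS_PER_YEAR, CohortTable, LifeTable, anniversary
from .hazards import ConstantHazard, GompertzMakehamHazard, HazardModel

__all__ = [
    "GroupSpec",
    "ANCESTOR_GROUP_PRESETS",
    "FRANCE_1875_LIKE",
    "FRANCE_2014_LIKE",
    "generate_supercentenarian_register",
    "generate_ancestor_cohorts",
    "generate_life_table",
]

SUPERCENTENARIAN_ENTRY_AGE = 110.0

# Stylised Gompertz-Makeham stand-ins for 19th-century vs contemporary French
# period mortality: the historical table differs mainly in its much larger
# age-independent (Makeham) component — infections, accidents, childbirth —
# not in the old-age Gompertz slope.
FRANCE_1875_LIKE = GompertzMakehamHazard(a=8e-5, b=0.09, c=0.012)
FRANCE_2014_LIKE = GompertzMakehamHazard(a=2.5e-5, b=0.095, c=0.0005)


@dataclass(frozen=True)
class GroupSpec:
    """One ancestor group: label, size, and its Gompertz-Makeham mortality."""

    label: str
    n: int
    model: HazardModel


# Three-group preset mirroring a genealogy of ~30 ancestors: the craftsman
# line and its in-laws share a low background hazard (prosperous households),
# while the remaining ancestors face a tenfold higher age-independent hazard.
# The Gompertz (old-age) parameters are deliberately identical across groups:
# the lifespan gap is an early/mid-life environment effect, not longevity.
ANCESTOR_GROUP_PRESETS: Tuple[GroupSpec, ...] = (
    GroupSpec("shipwrights", 10, GompertzMakehamHazard(a=3e-5, b=0.09, c=0.002)),
    GroupSpec("shipwrights_parents", 10, GompertzMakehamHazard(a=3e-5, b=0.09, c=0.002)),
    GroupSpec("other_ancestors", 10, GompertzMakehamHazard(a=3e-5, b=0.09, c=0.01)),
)


def _uniform_dates(rng: np.random.Generator, window, n: int) -> list:
    start, end = (dt.date.fromisoformat(d) if isinstance(d, str) else d for d in window)
    if end < start:
        raise ValueError(f"empty birth window {start}..{end}")
    lo, hi = start.toordinal(), end.toordinal()
    return [dt.date.fromordinal(int(o)) for o in rng.integers(lo, hi + 1, size=n)]


def generate_supercentenarian_register(
    n: int = 80,
    birth_window=("1860-01-01", "1875-12-31"),
    model: Optional[HazardModel] = None,
    seed=None,
) -> CohortTable:
    """Synthetic validated-supercentenarian register.

    ``n`` individuals with uniform birth dates in ``birth_window`` enter the
    register at their 110th birthday; residual lifespans beyond entry are
    drawn from ``model`` (default: constant hazard with annual survival 0.5,
    the plateau convention).  All records are deceased.
    """
    n = int(n)
    if n < 1:
        raise ValueError("register size n must be >= 1")
    if model is None:
        model = ConstantHazard(0.5, entry_age=SUPERCENTENARIAN_ENTRY_AGE)
    rng = np.random.default_rng(seed)
    births = _uniform_dates(rng, birth_window, n)
    residuals = model.sample_lifespans(n, rng=rng)
    rows = []
    for i, (b, r) in enumerate(zip(births, residuals)):
        entry_date = anniversary(b, 110)
        death = entry_date + dt.timedelta(days=int(round(r * DAYS_PER_YEAR)))
        rows.append(
            {
                "id": f"sc{i:04d}",
                "birth_date": b,
                "death_date": death,
                "group": "register",
                "entry_age": SUPERCENTENARIAN_ENTRY_AGE,
            }
        )
    return CohortTable(pd.DataFrame(rows))


def generate_ancestor_cohorts(
    group_specs: Optional[Sequence[GroupSpec]] = None,
    seed=None,
    birth_window=("1723-01-01", "1838-12-31"),
) -> CohortTable:
    """Synthetic multi-group ancestor genealogy (one row per person).

    Each group's full lifespans are drawn from its own Gompertz-Makeham
    model.  With the default presets the third group's higher Makeham term
    produces a lower median lifespan through excess early-adult mortality
    while leaving old-age mortality identical across groups.
    """
    specs = tuple(group_specs) if group_specs is not None else ANCESTOR_GROUP_PRESETS
    if len(specs) == 0:
        raise ValueError("need at least one group spec")
    for s in specs:
        if s.n < 1:
            raise ValueError(f"group {s.label!r} has nonpositive size {s.n}")
    rng = np.random.default_rng(seed)
    rows = []
    for s in specs:
        births = _uniform_dates(rng, birth_window, s.n)
        spans = s.model.sample_lifespans(s.n, rng=rng)
        for i, (b, span) in enumerate(zip(births, spans)):
            days = max(1, int(round(span * DAYS_PER_YEAR)))
            rows.append(
                {
                    "id": f"{s.label}-{i:03d}",
                    "birth_date": b,
                    "death_date": b + dt.timedelta(days=days),
                    "group": s.label,
                }
            )
    return CohortTable(pd.DataFrame(rows))


def generate_life_table(
    model: HazardModel, max_age: int, label: str = ""
) -> LifeTable:
    """Period life table implied by a hazard model.

    ``qx = 1 - S(x+1)/S(x)`` per integer age ``x`` measured from the model's
    entry age; the final age is forced to ``qx = 1`` (closure).  If the
    model's survival underflows before ``max_age`` the table closes early.
    """
    max_age = int(max_age)
    if max_age < 1:
        raise ValueError("max_age must be >= 1")
    ages = np.arange(0, max_age + 1)
    s = np.asarray(model.survival(ages.astype(float)))
    qx = []
    for x in range(max_age + 1):
        if x == max_age or s[x] <= 0 or s[x + 1] <= 0:
            qx.append(1.0)
            ages = ages[: x + 1]
            break
        qx.append(1.0 - s[x + 1] / s[x])
    return LifeTable(ages=ages, qx=np.array(qx), label=label)
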