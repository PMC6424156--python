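"""Spurious mortality plateaus from normally distributed age errors.

If true ages at death follow a Gompertz law (exponentially increasing
hazard) but the *recorded* ages carry additive normal errors, the oldest
recorded ages are dominated by upwardly mis-recorded members of the much
larger younger bulk.  The hazard estimated from recorded ages therefore
flattens — and its log-slope falls below the true Gompertz slope — even
though the underlying force of mortality keeps rising.  Records whose
perturbed age falls below the register's entry age vanish from the at-risk
set entirely (they would never have been enrolled), which is the survivor
bias component of the artifact.

Hazard estimation uses the standard demographic occurrence/exposure rate on
one-year age bins: deaths in bin divided by person-years lived in the bin,
both computed from recorded ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .hazards import HazardModel

__all__ = ["PlateauExperiment", "run_plateau_experiment", "hazard_slope"]


@dataclass
class PlateauExperiment:
    """Observed (recorded-age) vs true hazard for one error level.

    ``observed_hazard`` is NaN in bins whose starting at-risk count falls
    below ``min_at_risk`` (reported absent, not zero).
    """

    true_model: HazardModel
    error_sd: float
    n: int
    bin_edges: np.ndarray
    deaths: np.ndarray
    exposure: np.ndarray
    at_risk: np.ndarray
    observed_hazard: np.ndarray
    true_hazard: np.ndarray
    n_recorded: int
    recorded_top_decile: Tuple[float, float]
    seed: object
    contamination: float
    min_at_risk: int

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.bin_midpoints,
                "true_hazard": self.true_hazard,
                "observed_hazard": self.observed_hazard,
                "deaths": self.deaths,
                "exposure": self.exposure,
                "at_risk": self.at_risk,
            }
        )

    def to_dict(self) -> dict:
        return {
            "error_sd": self.error_sd,
            "n": self.n,
            "n_recorded": self.n_recorded,
            "contamination": self.contamination,
            "min_at_risk": self.min_at_risk,
            "seed": self.seed,
            "recorded_top_decile": list(self.recorded_top_decile),
            "age": self.bin_midpoints.tolist(),
            "true_hazard": self.true_hazard.tolist(),
            "observed_hazard": [
                None if not np.isfinite(v) else v for v in self.observed_hazard
            ],
        }


def _person_years_above(sorted_ages: np.ndarray, edge: float, entry: float) -> float:
    """Total person-years lived above max(edge, entry) by the recorded cohort."""
    e = max(edge, entry)
    i = np.searchsorted(sorted_ages, e, side="right")
    return float(sorted_ages[i:].sum() - (sorted_ages.size - i) * e)


def run_plateau_experiment(
    true_model: HazardModel,
    error_sd: float,
    n: int,
    age_grid: Optional[np.ndarray] = None,
    seed=None,
    min_at_risk: int = 50,
    contamination: float = 1.0,
) -> PlateauExperiment:
    """Simulate recorded-age hazards under additive normal age errors.

    Draws ``n`` true ages at death from ``true_model`` (entry age + residual
    lifespan), perturbs a ``contamination`` fraction of records with
    N(0, error_sd^2) errors, discards records whose recorded age falls below
    the entry age (they would not appear in the register), and estimates the
    hazard on one-year bins of recorded age as deaths / person-years.

    A fixed ``seed`` yields the same true ages and the same standard-normal
    error vector for every ``error_sd`` (errors are ``sd * z``), so results
    across error levels at one seed are common-random-number comparable.
    """
    n = int(n)
    if n < 1000:
        raise ValueError(f"need n >= 1000 for a stable hazard estimate, got {n}")
    if error_sd < 0:
        raise ValueError("error_sd must be >= 0")
    if not 0.0 < contamination <= 1.0:
        raise ValueError("contamination must be in (0, 1]")

    rng = np.random.default_rng(seed)
    entry = float(getattr(true_model, "entry_age", 0.0))
    true_ages = entry + true_model.sample_lifespans(n, rng=rng)
    z = rng.standard_normal(n)
    if contamination < 1.0:
        z = z * (rng.random(n) < contamination)
    recorded = true_ages + error_sd * z

    recorded = np.sort(recorded[recorded >= entry])
    if recorded.size == 0:
        raise ValueError("no records survive the entry-age filter")

    if age_grid is None:
        edges = np.arange(np.floor(entry), np.ceil(recorded[-1]) + 1.0)
    else:
        edges = np.asarray(age_grid, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("age_grid must be increasing bin edges")

    deaths, _ = np.histogram(recorded, bins=edges)
    at_risk = recorded.size - np.searchsorted(recorded, edges[:-1], side="left")
    pys = np.array([_person_years_above(recorded, e, entry) for e in edges])
    exposure = pys[:-1] - pys[1:]

    with np.errstate(divide="ignore", invalid="ignore"):
        observed = np.where(exposure > 0, deaths / exposure, np.nan)
    observed[at_risk < min_at_risk] = np.nan

    mids = 0.5 * (edges[:-1] + edges[1:])
    q90 = float(np.quantile(recorded, 0.9))
    return PlateauExperiment(
        true_model=true_model,
        error_sd=float(error_sd),
        n=n,
        bin_edges=edges,
        deaths=deaths,
        exposure=exposure,
        at_risk=at_risk,
        observed_hazard=observed,
        true_hazard=np.asarray(true_model.hazard(mids), dtype=float),
        n_recorded=int(recorded.size),
        recorded_top_decile=(q90, float(recorded[-1])),
        seed=seed,
        contamination=float(contamination),
        min_at_risk=int(min_at_risk),
    )


def hazard_slope(
    experiment: PlateauExperiment,
    age_window: Optional[Tuple[float, float]] = None,
    hazard: str = "observed",
    weighted: bool = True,
) -> float:
    """Least-squares log-slope (per year) of a hazard over an age window.

    ``age_window`` defaults to the top decile of recorded ages.  With
    ``weighted=True`` (default) bins are weighted by their death counts —
    the inverse-variance weighting for a log occurrence/exposure rate —
    which keeps sparse extreme-age bins from dominating the fit.  For a
    pure Gompertz ``hazard="true"`` the fit returns the slope parameter b
    exactly, weighted or not, because log-hazard is exactly linear in age.
    """
    if hazard not in ("observed", "true"):
        raise ValueError("hazard must be 'observed' or 'true'")
    lo, hi = age_window if age_window is not None else experiment.recorded_top_decile
    mids = experiment.bin_midpoints
    values = experiment.observed_hazard if hazard == "observed" else experiment.true_hazard
    sel = (mids >= lo) & (mids <= hi) & np.isfinite(values) & (values > 0)
    if sel.sum() < 3:
        raise ValueError(
            f"need at least 3 usable bins in window ({lo:.2f}, {hi:.2f}), "
            f"got {int(sel.sum())}"
        )
    w = None
    if weighted:
        w = np.sqrt(np.maximum(experiment.deaths[sel], 1).astype(float))
    return float(np.polyfit(mids[sel], np.log(values[sel]), 1, w=w)[0])
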