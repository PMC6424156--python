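# Methods

## The question and the model

A validated register contains N individuals who reached a plateau entry age
(110 years for supercentenarians). Under the mortality-plateau hypothesis
their residual lifespans are i.i.d. with a constant force of mortality
μ = −ln p per year, where p is the annual survival probability; p = 0.5 is
the empirically conventional plateau value. The probability that the
longest-lived member survives at least t further years is the exceedance
probability of the maximum of N i.i.d. exponentials,

    P(t, N) = 1 − (1 − p^t)^N.

`last_survivor_exceedance` evaluates this as `−expm1(N·log1p(−exp(t·ln p)))`,
which is exact to first order even when `p^t` is ~1e−300 and N is ~1e9; for
`N·p^t ≪ 1` it agrees with the linearisation `N·p^t` to well under 1%.

Time is in years throughout and residual lifespans are continuous; the
headline threshold 12.45 years is itself fractional (12 years + 164 days,
with decimal years defined as day count / 365.25).

## Monte Carlo verification

`estimate_exceedance_mc` simulates `reps` cohorts of N residual lifespans
from any hazard model and reports the fraction whose maximum reaches t,
with a Wilson score interval (chosen over Wald because the probabilities of
interest sit near 0, where Wald intervals collapse). The default is 10^5
cohorts; the acceptance script uses 10^6, which resolves a probability of
0.014 to about ±0.0002. Sampling is streamed in chunks of ≤4·10^6 draws so
memory stays flat.

Sampling is inverse-CDF throughout: exponential for the constant hazard,
the closed-form Gompertz inverse CDF conditioned on the entry age for the
Gompertz part, and — because the Gompertz–Makeham total hazard is a sum —
the Makeham term enters as a competing exponential risk (the residual
lifespan is the minimum of the two draws). This is exact; no root finding.

## Extinct-cohort survival curves

All cohorts analysed here are extinct (every member deceased), so the
empirical survival function needs no censoring machinery and coincides with
the Kaplan–Meier estimator; the test suite checks this equivalence against
lifelines on random small cohorts. Left truncation at a start age keeps
individuals whose lifespan is ≥ the start age in the risk set; a death
exactly at the start age drops the curve at t = 0, matching the convention
that the first recorded death defines the curve's first step. Ties drop
together. Curves are right-continuous step functions with S(0⁻) = 1,
reaching 0 for an extinct cohort.

Period life tables (integer ages, annual death probabilities qx, closure
qx = 1 at the final age) yield conditional survival from any start age by
the product S(k) = Π (1 − qx). Tables generated from a hazard model via
`qx = 1 − S(x+1)/S(x)` telescope exactly, so the round trip reproduces the
model's conditional survival to numerical precision.

`fit_constant_hazard` is the exponential MLE (deaths / person-years beyond
entry) with the exact interval from 2·rate·T ~ χ²(2D); exact rather than
asymptotic coverage matters at the n ≈ 30–80 sizes typical here.

## Simulation envelopes

`simulation_envelope` draws `reps` (default 2000) cohorts of size N,
evaluates each cohort's empirical survival on a common annual grid, and
takes pointwise order-statistic quantiles at (1±band)/2. Two deliberate
choices:

* **Annual grid, stopping where N·S(t) ≤ 0.02.** Beyond that point almost
  no simulated cohort has a survivor, the upper bound collapses to zero,
  and the envelope stops being informative about typical cohorts (any
  longer grid can be supplied via `time_grid=`, which is exactly how one
  probes whether a record tail sticks out).
* **Pointwise, not simultaneous.** The comparison this supports is visual
  (an observed curve overlaid on simulated populations), not a formal test.
  A full curve from the generating model escapes a pointwise 99% band
  somewhere with probability ~3–4% on the default grid; the calibration
  test asserts ≥95/100 cohorts stay inside.

At a 0.99 band a 12.45-year record among 80 plateau lifespans is *not*
pointwise-extreme (its exceedance probability, 0.0142, exceeds the 0.005
tail mass per grid point); it is flagged at a 0.95 band, and longer records
(≥ ~14 years) are flagged at 0.99. The tests exercise both regimes.

## The plateau artifact

`run_plateau_experiment` draws n true ages at death from a Gompertz(-Makeham)
law, adds independent N(0, sd²) errors to the recorded ages (a
contamination fraction, default 1, controls how many records are
perturbed), and discards records whose *recorded* age falls below the entry
age — such people would never have been enrolled in a 105+/110+ register,
and this selective loss is the survivor-bias half of the mechanism. The
hazard of the recorded ages is then estimated by the standard demographic
occurrence/exposure rate on one-year bins (deaths in bin / person-years in
bin), with bins reported absent (NaN) when the starting at-risk count is
below 50 (configurable).

`hazard_slope` summarises flattening as the least-squares slope of log
hazard against bin midpoint, by default over the top decile of recorded
ages and weighted by √(deaths) — inverse-variance weighting for a log
occurrence/exposure rate. Unweighted fitting is available, but the sparse
extreme-age bins then dominate the fit and the slope estimate becomes
several times noisier, obscuring the monotone distortion at small error
SDs. With error SD 0 the pipeline is an identity check: the estimated slope
recovers the Gompertz b within sampling error, and for the *true* hazard
the fit returns b exactly (log-linearity is exact).

One seed fixes both the true ages and the standard-normal error vector;
errors are `sd · z`, so runs at different error SDs under the same seed are
common-random-number comparable, which is how the monotone-flattening
property is asserted.

Expected magnitudes under the default truth (a = 1e−5, b = 0.1, n = 10^6):
top-decile observed log-slope ≈ 0.100, 0.095, 0.084, 0.072 at error SD 0,
1, 2, 3 years.

## Synthetic data

Generators cover every input the pipeline reads, with the structure of the
study conditions rather than any real microdata:

* **Register** — default n = 80 (the size of the register the headline
  probability refers to), uniform birth dates 1860–1875, entry at the 110th
  birthday, residual lifespans from ConstantHazard(0.5). Death dates are
  the entry anniversary plus the residual rounded to whole days; Feb 29
  birthdays take Feb 28 anniversaries.
* **Ancestor genealogy** — three groups of 10 (a craftsman line, its
  in-laws' parents, and the remaining ancestors) sharing identical Gompertz
  old-age parameters (a = 3e−5, b = 0.09) and differing only in the Makeham
  background hazard (c = 0.002 vs 0.01). This encodes the qualitative
  finding the module exists to reproduce: group lifespan differences driven
  by early/mid-life environment, not by old-age longevity. c ≈ 0.01 is a
  plausible 19th-century adult background hazard; c ≈ 0.002 a prosperous
  household's.
* **Life tables** — from any hazard model, including stylised stand-ins for
  1875-era (c = 0.012) and contemporary (c = 0.0005) French period
  mortality.

Same settings + seed give byte-identical CSV. What the generators do *not*
emulate: infant-mortality humps (lifespans are Gompertz–Makeham from
birth), cohort-vs-period distinctions, historical date structure, and the
actual lifespans behind the real genealogy — so tests passing on synthetic
inputs validate the estimators and the pipeline, not any empirical claim
about the historical families.

## Problem sizes

Defaults balance resolution against desk-scale runtimes: 10^5 Monte Carlo
cohorts for interactive use and 10^6 for the acceptance run; 2000-cohort
envelopes (4000 in the calibration test); plateau experiments at n = 10^6
for the headline property and 2·10^5 in unit tests. All stochastic results
are seeded and reproducible.

## Known limitations

* The exceedance analysis conditions on the register's size and entry age;
  it does not model age-ascertainment bias, register growth over time, or
  heterogeneity in p across individuals.
* The plateau-artifact experiment uses unbiased normal errors applied
  independently per record; correlated or systematically signed errors
  (e.g. identity substitution) are outside its scope.
* Envelopes are pointwise; no simultaneous-band or formal goodness-of-fit
  machinery is provided, deliberately.
* Censored records are rejected rather than handled: every analysis assumes
  extinct cohorts.
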