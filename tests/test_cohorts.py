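import datetime as dt

import numpy as np
import pytest

from plateaurecord import (
    CohortTable,
    ConstantHazard,
    GompertzMakehamHazard,
    SurvivalCurve,
    ValidationError,
    anniversary,
    curve_within_envelope,
    empirical_survival,
    fit_constant_hazard,
    generate_life_table,
    lifespan_years,
    lifetable_survival,
    simulation_envelope,
)

from conftest import cohort_from_lifespans, dkw_epsilon


class TestDates:
    def test_one_calendar_year_in_decimal_years(self):
        assert lifespan_years("1900-01-01", "1901-01-01") == pytest.approx(365 / 365.25)

    def test_death_not_after_birth_rejected(self):
        with pytest.raises(ValidationError):
            lifespan_years("1900-01-01", "1900-01-01")
        with pytest.raises(ValidationError):
            CohortTable.from_records([("x", "1900-05-01", "1899-01-01", "g")])

    def test_leap_day_anniversary_falls_back_to_feb_28(self):
        assert anniversary("1896-02-29", 5) == dt.date(1901, 2, 28)

    def test_cohort_rejects_censored_rows(self):
        with pytest.raises(ValidationError):
            CohortTable.from_records([("x", "1900-01-01", None, "g")])


class TestEmpiricalSurvival:
    def test_hand_enumerated_step_function(self):
        # deaths at 31, 40, 50; truncated at 31: drops to 2/3 at t=0,
        # 1/3 at t=9, 0 at t=19
        curve = empirical_survival(np.array([31.0, 40.0, 50.0]), start_age=31.0)
        assert np.allclose(curve.times, [0.0, 9.0, 19.0])
        assert np.allclose(curve.surv, [2 / 3, 1 / 3, 0.0])
        assert list(curve.at_risk) == [3, 2, 1]
        assert curve.evaluate(-0.1) == 1.0  # S(0^-) = 1
        assert curve.evaluate(8.9) == pytest.approx(2 / 3)
        assert curve.evaluate(19.0) == 0.0

    def test_cohort_table_input_with_truncation(self, small_cohort):
        curve = empirical_survival(small_cohort, start_age=35.0)
        assert curve.at_risk[0] == 2  # the age-31 death never reaches 35
        assert curve.surv[-1] == 0.0

    def test_single_individual(self):
        curve = empirical_survival(np.array([80.0]), start_age=50.0)
        assert np.allclose(curve.times, [30.0]) and curve.surv[0] == 0.0
        assert curve.evaluate(29.9) == 1.0

    def test_tied_deaths_drop_together(self):
        curve = empirical_survival(np.array([10.0, 10.0, 12.0]), start_age=0.0)
        assert np.allclose(curve.surv, [1 / 3, 0.0])

    def test_empty_risk_set_rejected(self):
        with pytest.raises(ValidationError):
            empirical_survival(np.array([30.0]), start_age=40.0)

    def test_matches_analytic_curve_within_dkw_band(self):
        n = 10_000
        spans = ConstantHazard(0.5).sample_lifespans(n, seed=21)
        curve = empirical_survival(spans, start_age=0.0)
        grid = np.linspace(0.05, 15.0, 150)
        diff = curve.evaluate(grid) - ConstantHazard(0.5).survival(grid)
        assert np.max(np.abs(diff)) < dkw_epsilon(n)

    def test_agrees_with_lifelines_kaplan_meier(self):
        from lifelines import KaplanMeierFitter

        spans = np.array([2.0, 5.0, 5.0, 7.5, 11.0])
        curve = empirical_survival(spans, start_age=0.0)
        kmf = KaplanMeierFitter().fit(spans)
        km = kmf.survival_function_at_times(curve.times).to_numpy()
        assert np.allclose(curve.surv, km, atol=1e-12)


class TestSurvivalCurveValidation:
    def test_increasing_survival_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalCurve(times=[1.0, 2.0], surv=[0.4, 0.6])

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalCurve(times=[2.0, 1.0], surv=[0.6, 0.4])

    def test_median(self):
        c = SurvivalCurve(times=[1.0, 2.0, 3.0], surv=[0.8, 0.5, 0.0])
        assert c.median() == 2.0


class TestLifeTable:
    def test_constant_qx_gives_geometric_survival(self):
        table = generate_life_table(ConstantHazard(0.5), 15, "flat")
        curve = lifetable_survival(table, 0)
        k = np.arange(1, curve.times.size)
        assert np.allclose(curve.surv[:-1], 0.5 ** k)  # geometric until closure
        assert curve.surv[-1] == 0.0  # closure (qx = 1) extinguishes the cohort

    def test_zero_mortality_until_closure(self):
        from plateaurecord import LifeTable

        table = LifeTable(ages=np.arange(5), qx=np.array([0, 0, 0, 0, 1.0]))
        curve = lifetable_survival(table, 0)
        assert np.allclose(curve.surv, [1, 1, 1, 1, 0])

    def test_gompertz_table_matches_conditional_closed_form(self):
        model = GompertzMakehamHazard(a=1e-5, b=0.1)
        table = generate_life_table(model, 120, "g")
        curve = lifetable_survival(table, 31)
        cond = GompertzMakehamHazard(a=1e-5, b=0.1, entry_age=31.0)
        k = np.arange(1.0, 61.0)
        assert np.max(np.abs(curve.surv[:60] / cond.survival(k) - 1)) < 0.02

    def test_start_age_outside_table_rejected(self):
        table = generate_life_table(ConstantHazard(0.5), 10)
        with pytest.raises(ValidationError):
            lifetable_survival(table, 11)

    def test_closure_required(self):
        from plateaurecord import LifeTable

        with pytest.raises(ValidationError):
            LifeTable(ages=np.arange(3), qx=np.array([0.1, 0.1, 0.5]))
        with pytest.raises(ValidationError):
            LifeTable(ages=np.array([0, 2, 3]), qx=np.array([0.1, 0.1, 1.0]))


class TestConstantHazardFit:
    def test_hand_mle(self):
        fit = fit_constant_hazard(np.array([1.0, 3.0]))
        assert fit.rate == pytest.approx(0.5)
        assert fit.annual_survival == pytest.approx(np.exp(-0.5))

    def test_single_lifespan(self):
        fit = fit_constant_hazard(np.array([4.0]))
        assert fit.rate == pytest.approx(0.25)

    def test_parameter_recovery_at_large_n(self):
        spans = ConstantHazard(0.5).sample_lifespans(10_000, seed=31)
        fit = fit_constant_hazard(spans)
        assert 0.49 <= fit.annual_survival <= 0.51

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValidationError):
            fit_constant_hazard(np.array([5.0]), entry_age=5.0)

    def test_ci_ordering(self):
        fit = fit_constant_hazard(np.array([0.5, 1.0, 2.0, 4.0]))
        assert fit.rate_ci[0] < fit.rate < fit.rate_ci[1]
        assert fit.annual_survival_ci[0] < fit.annual_survival < fit.annual_survival_ci[1]


class TestEnvelope:
    def test_contains_analytic_curve_pointwise(self):
        model = ConstantHazard(0.5)
        env = simulation_envelope(80, model, reps=2000, seed=17, band=0.99)
        analytic = SurvivalCurve(times=env.times[1:], surv=model.survival(env.times[1:]))
        assert curve_within_envelope(analytic, env).inside

    def test_widens_with_band(self):
        model = ConstantHazard(0.5)
        narrow = simulation_envelope(40, model, reps=1000, seed=2, band=0.90)
        wide = simulation_envelope(40, model, reps=1000, seed=2, band=0.99)
        assert np.all(wide.lower <= narrow.lower + 1e-12)
        assert np.all(wide.upper >= narrow.upper - 1e-12)

    def test_record_survivor_exits_envelope_tail(self):
        # 79 perfectly typical plateau lifespans (exponential quantiles, so
        # the curve body tracks the analytic survival) plus one 12.45-year
        # record: at the 95% band the upper bound hits zero before the
        # record tail does
        model = ConstantHazard(0.5)
        spans = -np.log(1.0 - (np.arange(79) + 0.5) / 79) / np.log(2.0)
        cohort = np.append(spans, 12.45)
        env95 = simulation_envelope(80, model, reps=2000, seed=5, band=0.95)
        check = curve_within_envelope(empirical_survival(cohort), env95)
        assert not check.inside
        assert check.first_violation_time >= 11.0

        # at the 99% band a 12.45-year record is *not* pointwise extreme
        # (P(max >= 12.45) is about 1.4%), but a 16-year one is
        grid = np.arange(0.0, 18.5, 1.0)
        env99 = simulation_envelope(80, model, reps=2000, seed=5, band=0.99, time_grid=grid)
        assert curve_within_envelope(empirical_survival(cohort), env99).inside
        cohort16 = np.append(spans, 16.0)
        check16 = curve_within_envelope(empirical_survival(cohort16), env99)
        assert not check16.inside and check16.first_violation_time >= 14.0

    def test_mismatched_start_age_rejected(self):
        env = simulation_envelope(10, ConstantHazard(0.5), reps=200, seed=0)
        curve = SurvivalCurve(times=[1.0], surv=[0.0], start_age=50.0)
        with pytest.raises(ValidationError):
            curve_within_envelope(curve, env)

    @pytest.mark.parametrize("band", [0.0, 1.0, -0.5])
    def test_invalid_band_rejected(self, band):
        with pytest.raises(ValueError):
            simulation_envelope(10, ConstantHazard(0.5), reps=200, seed=0, band=band)


def test_group_subsetting(small_cohort):
    table = cohort_from_lifespans([60.0, 70.0], group="a")
    frame = table.frame
    frame.loc[1, "group"] = "b"
    merged = CohortTable(frame)
    assert merged.groups == ["a", "b"]
    assert len(merged.subset("a")) == 1
    with pytest.raises(ValidationError):
        merged.subset("missing")
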