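import numpy as np
import pytest

from fifthcase.planner import (
    AnnualizationConfig,
    allocate,
    annual_extra_cases,
    build_scenario,
    fifth_success_rate,
    full_success_threshold_minutes,
    ochs_per_year,
    ochs_saved,
    scenario_table,
    week_skip_plan,
)
from fifthcase.predictor import predict_fifth_cases
from fifthcase.schedule_io import parse_clock


class TestOchsSaved:
    def test_full_success_saves_everything(self, study_profile):
        assert ochs_saved(1.0, study_profile) == pytest.approx(465.375, abs=1e-9)

    def test_realized_ssr_saves_nothing(self, study_profile):
        assert ochs_saved(301 / 761, study_profile) == pytest.approx(0.0, abs=1e-9)

    def test_77_percent_target(self, study_profile):
        # exact evaluation with x = 465.375/460 kept at full precision
        assert ochs_saved(0.77, study_profile) == pytest.approx(288.2998125, abs=1e-6)

    def test_below_realized_warns_but_returns(self, study_profile):
        with pytest.warns(UserWarning, match="negative savings"):
            saved = ochs_saved(0.30, study_profile)
        assert saved < 0

    def test_affine_increasing_in_target(self, study_profile):
        ys = np.linspace(0.4, 1.0, 7)
        vals = [ochs_saved(y, study_profile) for y in ys]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        diffs = np.diff(vals)
        assert np.allclose(diffs, diffs[0])  # affine in y

    def test_invalid_target_rejected(self, study_profile):
        for y in (0.0, -0.1, 1.01):
            with pytest.raises(ValueError):
                ochs_saved(y, study_profile)

    def test_per_year_conversion(self, study_profile):
        # 288.2998 h over 7.5 operating years -> 38 h 26 min per year
        per_year = ochs_per_year(ochs_saved(0.77, study_profile), AnnualizationConfig())
        hours = int(per_year)
        minutes = round((per_year - hours) * 60)
        assert (hours, minutes) == (38, 26)


class TestAllocate:
    def test_full_success_daily(self, study_profile):
        a = allocate(ochs_saved(1.0, study_profile), "daily", 761)
        assert a.seconds_per_fifth_day == 36 * 60 + 42
        assert str(a.end_time_benchmark) == "16:21:42"

    def test_77_percent_allocations(self, study_profile):
        saved = ochs_saved(0.77, study_profile)
        expected = {
            "daily": (22 * 60 + 44, "16:07:44"),
            "bidaily": (45 * 60 + 28, "16:30:28"),
            "weekly": (90 * 60 + 56, "17:15:56"),
        }
        for scheme, (secs, bench) in expected.items():
            a = allocate(saved, scheme, 761)
            assert a.seconds_per_fifth_day == secs
            assert str(a.end_time_benchmark) == bench

    def test_multiples_are_exact(self, study_profile):
        saved = ochs_saved(0.77, study_profile)
        d = allocate(saved, "daily", 761).seconds_per_fifth_day
        assert allocate(saved, "bidaily", 761).seconds_per_fifth_day == 2 * d
        assert allocate(saved, "weekly", 761).seconds_per_fifth_day == 4 * d

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            allocate(10.0, "monthly", 761)

    def test_conservation_against_annualized_savings(self, study_profile):
        # allocated minutes per year never exceed annualized savings beyond
        # the half-second-per-day quantization of the daily grant
        cfg = AnnualizationConfig()
        for y in (0.5, 0.77, 1.0):
            saved = max(0.0, ochs_saved(y, study_profile))
            annual_budget_sec = saved * 3600 / cfg.years_in_cohort
            days_per_year = study_profile.n_days / cfg.years_in_cohort
            for scheme, mult in (("daily", 1), ("bidaily", 2), ("weekly", 4)):
                a = allocate(saved, scheme, study_profile.n_days)
                granted = a.seconds_per_fifth_day * (days_per_year / mult)
                assert granted <= annual_budget_sec + 0.5 * days_per_year


class TestFifthSuccessRate:
    def test_extremes_and_median(self, synthetic_successful):
        ps = predict_fifth_cases(synthetic_successful)
        lo = min(p.seconds for p in ps.predictions)
        hi = max(p.seconds for p in ps.predictions)
        from fifthcase.schedule_io import ClockTime

        assert fifth_success_rate(ps, ClockTime(lo - 1)) == 0.0
        assert fifth_success_rate(ps, ClockTime(hi)) == 1.0
        med = int(np.median([p.seconds for p in ps.predictions]))
        assert fifth_success_rate(ps, ClockTime(med)) >= 0.5

    def test_monotone_in_benchmark(self, synthetic_successful):
        ps = predict_fifth_cases(synthetic_successful)
        benches = [parse_clock(t) for t in ("16:00", "16:30", "17:00", "17:30", "18:30")]
        rates = [fifth_success_rate(ps, b) for b in benches]
        assert rates == sorted(rates)

    def test_threshold_from_predictions(self, synthetic_successful):
        ps = predict_fifth_cases(synthetic_successful)
        thr = full_success_threshold_minutes(AnnualizationConfig(), ps)
        assert fifth_success_rate(ps, parse_clock("15:45") + round(thr * 60)) == 1.0


class TestWeekSkip:
    def test_study_pooling_two_per_three_weeks(self):
        plan = week_skip_plan(90 + 56 / 60, 135.0)
        assert (plan.successes_per_cycle, plan.cycle_weeks) == (2, 3)

    def test_no_skipping_needed_above_threshold(self):
        plan = week_skip_plan(140.0, 135.0)
        assert (plan.successes_per_cycle, plan.cycle_weeks) == (1, 1)

    def test_exact_half_threshold_pools_two_weeks(self):
        plan = week_skip_plan(67.5, 135.0)
        assert (plan.successes_per_cycle, plan.cycle_weeks) == (1, 2)

    def test_no_plan_without_savings(self):
        assert week_skip_plan(0.0, 135.0) is None
        assert week_skip_plan(-5.0, 135.0) is None


class TestAnnualExtraCases:
    def test_study_77_percent_count(self):
        cfg = AnnualizationConfig(full_success_threshold_minutes=135.0)
        cases, plan = annual_extra_cases(90 + 56 / 60, 135.0, cfg)
        assert cases == 35  # round(52 * 2/3)
        assert (plan.successes_per_cycle, plan.cycle_weeks) == (2, 3)

    def test_study_full_success_count(self):
        cfg = AnnualizationConfig(full_success_threshold_minutes=135.0)
        cases, plan = annual_extra_cases(146.8, 135.0, cfg)
        # 52 guaranteed weekly cases + floor(52*11/119) surplus-funded cases
        assert cases == 56

    def test_zero_savings_zero_cases(self):
        cfg = AnnualizationConfig(full_success_threshold_minutes=135.0)
        assert annual_extra_cases(0.0, 135.0, cfg) == (0, None)

    def test_monotone_in_target_ssr(self, study_profile, synthetic_successful):
        ps = predict_fifth_cases(synthetic_successful)
        cfg = AnnualizationConfig(full_success_threshold_minutes=135.0)
        counts = [
            build_scenario(y, "weekly_skip", study_profile, ps, cfg).extra_cases_per_year
            for y in (0.5, 0.65, 0.77, 0.9, 1.0)
        ]
        assert counts == sorted(counts)


class TestScenarioAssembly:
    def test_table_shape_and_columns(self, study_profile, synthetic_successful):
        ps = predict_fifth_cases(synthetic_successful)
        cfg = AnnualizationConfig(full_success_threshold_minutes=135.0)
        tab = scenario_table([0.77, 1.0], ["daily", "weekly", "weekly_skip"],
                             study_profile, ps, cfg)
        assert len(tab) == 6
        assert set(tab["scheme"]) == {"daily", "weekly", "weekly_skip"}
        assert (tab["ochs_saved_hours"] >= 0).all()

    def test_rate_non_decreasing_in_grant(self, study_profile, synthetic_successful):
        ps = predict_fifth_cases(synthetic_successful)
        cfg = AnnualizationConfig(full_success_threshold_minutes=135.0)
        rows = [
            build_scenario(0.77, s, study_profile, ps, cfg)
            for s in ("daily", "bidaily", "weekly")
        ]
        rates = [r.fifth_success_rate for r in rows]
        assert rates == sorted(rates)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnnualizationConfig(weeks_per_year=0)
        with pytest.raises(ValueError):
            AnnualizationConfig(full_success_threshold_minutes=-1)
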