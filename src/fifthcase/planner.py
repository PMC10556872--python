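"""Overtime-cost-hours savings and fifth-case scenario planning.

Raising the cohort surgical success rate (SSR) from its realized value to a
target y saves overtime-cost hours

    OCHS(y) = T - N * x * (1 - y)

where T is the cohort's total overtime-cost hours, N its day count, and x the
overtime-cost hours per unsuccessful day (kept at full precision — T / n_unsuccessful,
never the rounded "about an hour").  At y = 1 the whole total T is saved; at
the realized SSR nothing is.

The saved hours are converted into extra end-of-day minutes for candidate
fifth-case days under four pooling schemes: daily (every day gets a grant),
bi-daily (2x on half the days), weekly (4x on one day of a 4-OR-day week),
and week-skip (skipping whole weeks' grants to push pooled days past the
full-success threshold).  The daily grant is quantized to whole seconds and
the bi-daily/weekly grants are exact 2x/4x multiples of that quantized value
— extra-time grants are scheduled to the second, and the multiples then stay
mutually consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from fifthcase.classification import DEFAULT_CUTOFF, CohortOvertimeProfile
from fifthcase.predictor import PredictionSet
from fifthcase.schedule_io import ClockTime, round_half_up

SCHEME_MULTIPLIERS = {"daily": 1, "bidaily": 2, "weekly": 4}
SCHEMES = ("daily", "bidaily", "weekly", "weekly_skip")


@dataclass(frozen=True)
class AnnualizationConfig:
    """Calendar conventions for turning cohort savings into yearly cases.

    ``full_success_threshold_minutes`` is the grant (minutes past the cutoff)
    at which every predicted fifth case meets its deadline; leave ``None`` to
    derive it from a prediction set (max prediction minus cutoff).
    ``years_in_cohort`` converts cohort totals to per-year rates.
    """

    weeks_per_year: float = 52.0
    or_days_per_week: int = 4
    years_in_cohort: float = 7.5
    full_success_threshold_minutes: float | None = None
    max_cycle_weeks: int = 8
    mean_case_minutes: float = 119.0

    def __post_init__(self) -> None:
        if (
            self.weeks_per_year <= 0
            or self.or_days_per_week <= 0
            or self.years_in_cohort <= 0
            or self.max_cycle_weeks < 1
            or self.mean_case_minutes <= 0
        ):
            raise ValueError("AnnualizationConfig fields must be strictly positive")
        if (
            self.full_success_threshold_minutes is not None
            and self.full_success_threshold_minutes <= 0
        ):
            raise ValueError("full_success_threshold_minutes must be positive")


@dataclass(frozen=True)
class Allocation:
    scheme: str
    seconds_per_fifth_day: int
    end_time_benchmark: ClockTime

    @property
    def minutes_per_fifth_day(self) -> float:
        return self.seconds_per_fifth_day / 60.0


@dataclass(frozen=True)
class WeekSkipPlan:
    successes_per_cycle: int
    cycle_weeks: int

    @property
    def rate_per_week(self) -> float:
        return self.successes_per_cycle / self.cycle_weeks


@dataclass(frozen=True)
class ScenarioPlan:
    target_ssr: float
    ochs_saved_hours: float
    scheme: str
    minutes_per_fifth_day: float
    end_time_benchmark: ClockTime
    fifth_success_rate: float | None
    extra_cases_per_year: int
    week_skip: WeekSkipPlan | None = None


def ochs_saved(y: float, profile: CohortOvertimeProfile) -> float:
    """Overtime-cost hours saved by raising the SSR to ``y`` (in hours)."""
    if not 0 < y <= 1:
        raise ValueError("target SSR must lie in (0, 1]")
    x = profile.ochs_per_unsuccessful_day
    if x is None:
        return 0.0  # no unsuccessful days: nothing left to save
    saved = profile.total_ochs_hours - profile.n_days * x * (1.0 - y)
    if y < profile.ssr:
        warnings.warn(
            f"target SSR {y:.4f} below the realized SSR {profile.ssr:.4f}: "
            "negative savings",
            stacklevel=2,
        )
    return saved


def ochs_per_year(ochs_hours: float, cfg: AnnualizationConfig) -> float:
    """Cohort savings expressed per operating year."""
    return ochs_hours / cfg.years_in_cohort


def allocate(
    ochs_hours: float,
    scheme: str,
    n_days: int,
    cutoff: ClockTime = DEFAULT_CUTOFF,
) -> Allocation:
    """Convert saved hours into an extra-minutes grant and end-time benchmark.

    The daily grant is ``ochs_hours * 3600 / n_days`` seconds, quantized
    half-up to a whole second; bi-daily and weekly grants are exact 2x and 4x
    multiples of the quantized daily grant.  The benchmark is the cutoff plus
    the grant.
    """
    if ochs_hours < 0:
        raise ValueError("cannot allocate negative savings")
    if scheme not in SCHEME_MULTIPLIERS:
        raise ValueError(
            f"unknown scheme {scheme!r}: expected one of {sorted(SCHEME_MULTIPLIERS)}"
        )
    daily_seconds = round_half_up(ochs_hours * 3600.0 / n_days)
    seconds = SCHEME_MULTIPLIERS[scheme] * daily_seconds
    return Allocation(
        scheme=scheme,
        seconds_per_fifth_day=seconds,
        end_time_benchmark=cutoff + seconds,
    )


def fifth_success_rate(predictions: PredictionSet, benchmark: ClockTime) -> float:
    """Fraction of predicted fifth cases at or before the benchmark."""
    if len(predictions) == 0:
        raise ValueError("empty prediction set")
    return predictions.fraction_at_or_before(benchmark)


def full_success_threshold_minutes(
    cfg: AnnualizationConfig,
    predictions: PredictionSet | None = None,
    cutoff: ClockTime = DEFAULT_CUTOFF,
) -> float:
    """Grant (minutes past cutoff) guaranteeing a 100% predicted success rate."""
    if cfg.full_success_threshold_minutes is not None:
        return cfg.full_success_threshold_minutes
    if predictions is None:
        raise ValueError(
            "need either cfg.full_success_threshold_minutes or a prediction set"
        )
    return (predictions.max_prediction.seconds - cutoff.seconds) / 60.0


def week_skip_plan(
    weekly_minutes: float,
    threshold_minutes: float,
    max_cycle_weeks: int = 8,
) -> WeekSkipPlan | None:
    """Best pooling cycle: s fully-funded fifth-case days per c weeks.

    Scans cycle lengths c = 1..max_cycle_weeks; pooling c weekly grants funds
    s = floor(c * weekly / threshold) days at the full-success threshold.
    Returns the cycle maximizing the success rate s/c (ties to the shortest
    cycle), or ``None`` when no cycle funds a single day.
    """
    if weekly_minutes <= 0:
        return None
    if threshold_minutes <= 0:
        raise ValueError("threshold_minutes must be positive")
    if weekly_minutes >= threshold_minutes:
        return WeekSkipPlan(successes_per_cycle=1, cycle_weeks=1)
    best: WeekSkipPlan | None = None
    for c in range(1, max_cycle_weeks + 1):
        s = math.floor(c * weekly_minutes / threshold_minutes)
        if s < 1:
            continue
        cand = WeekSkipPlan(successes_per_cycle=s, cycle_weeks=c)
        if best is None or cand.rate_per_week > best.rate_per_week + 1e-12:
            best = cand
    return best


def annual_extra_cases(
    weekly_minutes: float,
    threshold_minutes: float,
    cfg: AnnualizationConfig,
) -> tuple[int, WeekSkipPlan | None]:
    """Extra fully-funded fifth cases per year from weekly-pooled savings.

    When the weekly grant meets the full-success threshold, every week hosts
    one guaranteed fifth case, and the per-week surplus (truncated to whole
    minutes — grants are scheduled in whole minutes) pools across the year
    into ``floor(weeks * surplus / mean_case_minutes)`` additional cases.
    Otherwise the week-skip plan yields ``round(weeks * s / c)`` cases.
    Returns ``(cases, week_skip_plan_or_None)``.
    """
    if weekly_minutes <= 0:
        return 0, None
    if weekly_minutes >= threshold_minutes:
        surplus_whole_min = math.floor(weekly_minutes - threshold_minutes)
        extra = math.floor(
            cfg.weeks_per_year * surplus_whole_min / cfg.mean_case_minutes
        )
        return int(round_half_up(cfg.weeks_per_year)) + extra, WeekSkipPlan(1, 1)
    plan = week_skip_plan(weekly_minutes, threshold_minutes, cfg.max_cycle_weeks)
    if plan is None:
        return 0, None
    return round_half_up(cfg.weeks_per_year * plan.rate_per_week), plan


def build_scenario(
    target_ssr: float,
    scheme: str,
    profile: CohortOvertimeProfile,
    predictions: PredictionSet | None = None,
    cfg: AnnualizationConfig = AnnualizationConfig(),
    cutoff: ClockTime = DEFAULT_CUTOFF,
) -> ScenarioPlan:
    """Assemble one (target SSR, scheme) scenario end to end."""
    saved = max(0.0, ochs_saved(target_ssr, profile))
    base_scheme = "weekly" if scheme == "weekly_skip" else scheme
    alloc = allocate(saved, base_scheme, profile.n_days, cutoff)
    weekly_alloc = allocate(saved, "weekly", profile.n_days, cutoff)
    threshold = full_success_threshold_minutes(cfg, predictions, cutoff)
    rate = (
        fifth_success_rate(predictions, alloc.end_time_benchmark)
        if predictions is not None
        else None
    )
    skip: WeekSkipPlan | None = None
    if scheme == "weekly_skip":
        cases, skip = annual_extra_cases(
            weekly_alloc.minutes_per_fifth_day, threshold, cfg
        )
        if skip is not None:
            rate = 1.0 if predictions is not None else rate
    elif scheme == "weekly":
        cases, skip = annual_extra_cases(
            weekly_alloc.minutes_per_fifth_day, threshold, cfg
        )
        if weekly_alloc.minutes_per_fifth_day < threshold:
            # weekly grants alone do not guarantee success; only the skip
            # variant converts them into fully-funded cases
            cases = 0
            skip = None
    else:
        # per-day grants below the threshold fund no guaranteed case
        per_day = alloc.minutes_per_fifth_day
        if per_day >= threshold:
            days_per_year = profile.n_days / cfg.years_in_cohort
            cases = math.floor(days_per_year / SCHEME_MULTIPLIERS[base_scheme])
        else:
            cases = 0
    return ScenarioPlan(
        target_ssr=target_ssr,
        ochs_saved_hours=saved,
        scheme=scheme,
        minutes_per_fifth_day=alloc.minutes_per_fifth_day,
        end_time_benchmark=alloc.end_time_benchmark,
        fifth_success_rate=rate,
        extra_cases_per_year=cases,
        week_skip=skip,
    )


def scenario_table(
    target_ssrs,
    schemes,
    profile: CohortOvertimeProfile,
    predictions: PredictionSet | None = None,
    cfg: AnnualizationConfig = AnnualizationConfig(),
    cutoff: ClockTime = DEFAULT_CUTOFF,
):
    """One row per (target SSR, scheme): the machine-readable scenario report."""
    import pandas as pd

    from fifthcase.schedule_io import format_duration

    rows = []
    for y in target_ssrs:
        for scheme in schemes:
            p = build_scenario(y, scheme, profile, predictions, cfg, cutoff)
            rows.append(
                {
                    "target_ssr": y,
                    "scheme": scheme,
                    "ochs_saved_hours": p.ochs_saved_hours,
                    "minutes_per_fifth_day": p.minutes_per_fifth_day,
                    "grant_hms": format_duration(p.minutes_per_fifth_day * 60),
                    "end_time_benchmark": str(p.end_time_benchmark),
                    "fifth_success_rate": p.fifth_success_rate,
                    "extra_cases_per_year": p.extra_cases_per_year,
                }
            )
    return pd.DataFrame(rows)
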