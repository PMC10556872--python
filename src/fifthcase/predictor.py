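"""Per-day linear extrapolation of out-of-room times.

Each successful day gets its own ordinary least-squares line

    y = w1 * x + w0

with case number x in {1..4} as the regressor and the out-of-room time y in
seconds as the response.  The slope w1 is that day's average case duration;
the intercept w0 absorbs the day's start time.  With four points per day the
normal equations are solved in closed form — no iterative optimiser, no
regularisation — and the fifth-case completion time is the line evaluated at
x = 5.  There is deliberately no pooling across days: days differ in start
time and pace, and the per-day line is the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fifthcase.schedule_io import ClockTime, DayRecord, round_half_up, times_matrix

#: default thresholds summarised for every prediction set
DEFAULT_THRESHOLDS = (ClockTime.from_hms(17, 45), ClockTime.from_hms(18, 0))


@dataclass(frozen=True)
class LinearDayModel:
    """A fitted per-day line: intercept/slope in seconds, plus fit MAE."""

    day_id: str
    w0: float
    w1: float
    fit_mae_seconds: float
    n_fit: int

    def predicted_seconds(self, case_number: int) -> float:
        return self.w0 + self.w1 * case_number


def _ols_closed_form(y: np.ndarray) -> tuple[float, float]:
    """Least squares of y on x = 1..k via the closed-form normal equations.

    For equally spaced x, Sxx = k(k^2-1)/12 and
    w1 = sum((x - xbar) y) / Sxx, w0 = ybar - w1 * xbar.
    """
    k = len(y)
    x = np.arange(1, k + 1, dtype=float)
    xbar = (k + 1) / 2.0
    sxx = k * (k * k - 1) / 12.0
    w1 = float(np.dot(x - xbar, y) / sxx)
    w0 = float(np.mean(y) - w1 * xbar)
    return w0, w1


def fit_day_line(day: DayRecord, fit_cases: int = 4) -> LinearDayModel:
    """Fit the day's line to its first ``fit_cases`` out-of-room times."""
    if fit_cases < 2:
        raise ValueError("fit_day_line needs at least 2 cases for a line")
    if fit_cases > 4:
        raise ValueError("a DayRecord holds 4 observed cases")
    y = np.array(day.out_of_room_seconds[:fit_cases], dtype=float)
    w0, w1 = _ols_closed_form(y)
    x = np.arange(1, fit_cases + 1, dtype=float)
    mae = float(np.mean(np.abs(y - (w0 + w1 * x))))
    return LinearDayModel(
        day_id=day.day_id, w0=w0, w1=w1, fit_mae_seconds=mae, n_fit=fit_cases
    )


def predict_case(model: LinearDayModel, case_number: int) -> ClockTime:
    """Evaluate the day's line at a case number, rounded to the second."""
    if case_number < 1:
        raise ValueError("case_number must be >= 1")
    raw = model.predicted_seconds(case_number)
    if not 0 <= raw < 172_800:
        raise ValueError(
            f"day {model.day_id}: predicted time {raw:.0f} s for case "
            f"{case_number} outside [0, 48 h) — pathological input"
        )
    return ClockTime(round_half_up(raw))


def fit_lines_matrix(times: np.ndarray, fit_cases: int = 4):
    """Vectorised closed-form OLS over an (n_days, >=fit_cases) time matrix.

    Returns ``(w0, w1, fit_mae)`` arrays; identical arithmetic to
    :func:`fit_day_line`, used by the cohort-level entry points.
    """
    y = np.asarray(times, dtype=float)[:, :fit_cases]
    k = fit_cases
    x = np.arange(1, k + 1, dtype=float)
    xbar = (k + 1) / 2.0
    sxx = k * (k * k - 1) / 12.0
    w1 = (y @ (x - xbar)) / sxx
    w0 = y.mean(axis=1) - w1 * xbar
    resid = y - (w0[:, None] + np.outer(w1, x))
    return w0, w1, np.abs(resid).mean(axis=1)


@dataclass(frozen=True)
class PredictionSummary:
    mean_seconds: float
    median_seconds: float
    sd_seconds: float
    ci95_low_seconds: float
    ci95_high_seconds: float
    fractions_at_or_before: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PredictionSet:
    """One fifth-case prediction per modelled day, with distribution summary."""

    day_ids: tuple
    predictions: tuple  # ClockTime per day, second-rounded
    pred_seconds: np.ndarray  # unrounded, for distribution statistics
    models: tuple
    summary: PredictionSummary

    def __len__(self) -> int:
        return len(self.predictions)

    def fraction_at_or_before(self, t: ClockTime) -> float:
        return float(np.mean([p.seconds <= t.seconds for p in self.predictions]))

    @property
    def max_prediction(self) -> ClockTime:
        return max(self.predictions)


def predict_fifth_cases(
    successful_days: list[DayRecord],
    thresholds: tuple = DEFAULT_THRESHOLDS,
) -> PredictionSet:
    """Fit each day on its 4 cases and extrapolate the 5th completion time.

    The summary reports mean, median, population SD, a 95% normal CI of the
    mean (mean +/- 1.96 sd/sqrt(n)), and the fraction of predictions at or
    before each queried threshold.
    """
    if not successful_days:
        raise ValueError("predict_fifth_cases requires at least one day")
    mat = times_matrix(successful_days)
    w0, w1, mae = fit_lines_matrix(mat, fit_cases=4)
    raw = w0 + 5.0 * w1
    models = tuple(
        LinearDayModel(d.day_id, float(a), float(b), float(m), 4)
        for d, a, b, m in zip(successful_days, w0, w1, mae)
    )
    preds = tuple(predict_case(m, 5) for m in models)
    n = len(preds)
    sd = float(np.std(raw, ddof=0))
    mean = float(np.mean(raw))
    half = 1.96 * sd / np.sqrt(n)
    fractions = {
        str(t): float(np.mean([p.seconds <= t.seconds for p in preds]))
        for t in thresholds
    }
    summary = PredictionSummary(
        mean_seconds=mean,
        median_seconds=float(np.median(raw)),
        sd_seconds=sd,
        ci95_low_seconds=mean - half,
        ci95_high_seconds=mean + half,
        fractions_at_or_before=fractions,
    )
    return PredictionSet(
        day_ids=tuple(d.day_id for d in successful_days),
        predictions=preds,
        pred_seconds=raw,
        models=models,
        summary=summary,
    )


def mean_duration_baseline(
    successful_days: list[DayRecord],
    mean_case_minutes: float = 119.0,
    success_time: ClockTime = ClockTime.from_hms(17, 45),
) -> float:
    """Fraction of days whose 4th time + a fixed mean case duration meets a deadline.

    A deliberately naive comparator: it assigns every hypothetical 5th case
    the cohort-wide mean duration, ignoring that spread grows with case
    number.  On a cohort of successful days (4th case <= 15:45) with the
    defaults it is trivially 1.0 — which is exactly why it is unrealistic.
    """
    if not successful_days:
        raise ValueError("mean_duration_baseline requires at least one day")
    add = mean_case_minutes * 60.0
    hits = [
        d.fourth_out_of_room.seconds + add <= success_time.seconds
        for d in successful_days
    ]
    return float(np.mean(hits))
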