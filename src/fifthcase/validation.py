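"""Ground-truth-free validation of the per-day lines.

No fifth-case ground truth exists, so model quality is inferred two ways:

* **Back-prediction** — refit each successful day's line on its first 2 (or
  3) cases only and score the held-out 3rd (or 4th) case with the mean
  absolute error MAE = (1/n) sum |y_i - yhat_i|.
* **Fit MAE** — the mean absolute residual of each day's 4-point line,
  measuring how linear successful days actually are.

Back-prediction extrapolates, fit MAE interpolates, so the former is expected
to exceed the latter on any noisy cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from fifthcase.predictor import fit_lines_matrix
from fifthcase.schedule_io import DayRecord, times_matrix


@dataclass(frozen=True)
class ValidationReport:
    scheme: str
    day_ids: tuple
    per_day_abs_errors: np.ndarray  # seconds
    mae_seconds: float
    sd_seconds: float
    ci95_low: float
    ci95_high: float


def mean_ci95(values, method: str = "normal") -> tuple[float, float]:
    """95% confidence interval for the mean of ``values``.

    ``normal`` uses mean +/- 1.96 sd/sqrt(n) (population sd); ``t`` uses the
    Student-t interval.  At n in the hundreds the two are indistinguishable.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("mean_ci95 needs at least 2 values")
    m = float(v.mean())
    if method == "normal":
        half = 1.96 * float(v.std(ddof=0)) / np.sqrt(v.size)
        return m - half, m + half
    if method == "t":
        se = float(v.std(ddof=1)) / np.sqrt(v.size)
        tcrit = float(stats.t.ppf(0.975, v.size - 1))
        return m - tcrit * se, m + tcrit * se
    raise ValueError(f"unknown CI method {method!r}")


def _report(scheme: str, day_ids, errors: np.ndarray, ci_method: str) -> ValidationReport:
    lo, hi = mean_ci95(errors, ci_method)
    return ValidationReport(
        scheme=scheme,
        day_ids=tuple(day_ids),
        per_day_abs_errors=errors,
        mae_seconds=float(errors.mean()),
        sd_seconds=float(errors.std(ddof=0)),
        ci95_low=lo,
        ci95_high=hi,
    )


def backpredict(
    successful_days: list[DayRecord],
    target_case: int,
    ci_method: str = "normal",
) -> ValidationReport:
    """Hold out case ``target_case`` (3 or 4), fit on the earlier cases, score it."""
    if target_case not in (3, 4):
        raise ValueError("target_case must be 3 or 4")
    if len(successful_days) < 2:
        raise ValueError("backpredict needs at least 2 days")
    mat = times_matrix(successful_days)
    k = target_case - 1
    w0, w1, _ = fit_lines_matrix(mat, fit_cases=k)
    predicted = w0 + w1 * target_case
    errors = np.abs(mat[:, target_case - 1] - predicted)
    return _report(
        f"backpredict_{target_case}",
        (d.day_id for d in successful_days),
        errors,
        ci_method,
    )


def fit_mae_report(
    successful_days: list[DayRecord], ci_method: str = "normal"
) -> ValidationReport:
    """Per-day mean absolute residual of the 4-point line, aggregated cohort-wide."""
    if len(successful_days) < 2:
        raise ValueError("fit_mae_report needs at least 2 days")
    mat = times_matrix(successful_days)
    _, _, mae = fit_lines_matrix(mat, fit_cases=4)
    return _report(
        "fit_mae", (d.day_id for d in successful_days), mae, ci_method
    )


def error_histogram(report: ValidationReport, bin_width_seconds: int = 60):
    """Binned counts of per-day absolute errors (seconds)."""
    import pandas as pd

    starts = (report.per_day_abs_errors // bin_width_seconds).astype(int)
    uniq, counts = np.unique(starts, return_counts=True)
    return pd.DataFrame(
        {
            "bin_start_seconds": uniq * bin_width_seconds,
            "count": counts,
        }
    )
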