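"""Day success classification and cohort descriptive statistics.

A day succeeds when its 4th case is out of the room at or before the cutoff
(15:45 by default — the scheduled 15:30 finish plus the 15-minute
overtime-pay buffer; the boundary instant itself counts as success).  Spare
time accrues on successful days, overtime on unsuccessful ones, and
*overtime-cost hours* are overtime hours multiplied by the 1.5x overtime pay
rate.  All aggregation is cohort-level: spare time on good days never offsets
overtime on bad ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fifthcase.schedule_io import ClockTime, DayRecord, times_matrix

DEFAULT_CUTOFF = ClockTime.from_hms(15, 45)
DEFAULT_OVERTIME_RATE = 1.5


@dataclass(frozen=True)
class DayOutcome:
    day_id: str
    successful: bool
    spare_seconds: int
    overtime_seconds: int

    def __post_init__(self) -> None:
        if self.successful:
            assert self.overtime_seconds == 0 and self.spare_seconds >= 0
        else:
            assert self.spare_seconds == 0 and self.overtime_seconds > 0


@dataclass(frozen=True)
class CohortOvertimeProfile:
    """Cohort-level success and overtime-cost aggregates.

    ``ochs_per_unsuccessful_day`` (the per-day overtime-cost-hour burden that
    the savings formula scales by) is ``None`` when the cohort has no
    unsuccessful days — undefined, not zero.
    """

    n_days: int
    n_successful: int
    ssr: float
    total_spare_hours: float
    total_overtime_hours: float
    overtime_rate: float
    total_ochs_hours: float
    ochs_per_unsuccessful_day: float | None
    mean_spare_seconds_successful: float | None

    @property
    def n_unsuccessful(self) -> int:
        return self.n_days - self.n_successful

    @classmethod
    def from_totals(
        cls,
        n_days: int,
        n_successful: int,
        total_ochs_hours: float,
        total_spare_hours: float = 0.0,
        overtime_rate: float = DEFAULT_OVERTIME_RATE,
    ) -> "CohortOvertimeProfile":
        """Build a profile from published aggregates instead of raw days."""
        n_unsucc = n_days - n_successful
        return cls(
            n_days=n_days,
            n_successful=n_successful,
            ssr=n_successful / n_days,
            total_spare_hours=total_spare_hours,
            total_overtime_hours=total_ochs_hours / overtime_rate,
            overtime_rate=overtime_rate,
            total_ochs_hours=total_ochs_hours,
            ochs_per_unsuccessful_day=(
                total_ochs_hours / n_unsucc if n_unsucc else None
            ),
            mean_spare_seconds_successful=(
                total_spare_hours * 3600 / n_successful if n_successful else None
            ),
        )


def classify_day(day: DayRecord, cutoff: ClockTime = DEFAULT_CUTOFF) -> DayOutcome:
    """Classify one day against the cutoff (at-or-before counts successful)."""
    last = day.fourth_out_of_room.seconds
    delta = cutoff.seconds - last
    if delta >= 0:
        return DayOutcome(day.day_id, True, spare_seconds=delta, overtime_seconds=0)
    return DayOutcome(day.day_id, False, spare_seconds=0, overtime_seconds=-delta)


def split_successful(
    days: list[DayRecord], cutoff: ClockTime = DEFAULT_CUTOFF
) -> tuple[list[DayRecord], list[DayRecord]]:
    """Partition days into (successful, unsuccessful) groups."""
    succ = [d for d in days if classify_day(d, cutoff).successful]
    unsucc = [d for d in days if not classify_day(d, cutoff).successful]
    return succ, unsucc


def cohort_profile(
    days: list[DayRecord],
    cutoff: ClockTime = DEFAULT_CUTOFF,
    overtime_rate: float = DEFAULT_OVERTIME_RATE,
) -> CohortOvertimeProfile:
    """Aggregate outcomes into a :class:`CohortOvertimeProfile`."""
    if not days:
        raise ValueError("cohort_profile requires at least one day")
    outcomes = [classify_day(d, cutoff) for d in days]
    n_succ = sum(o.successful for o in outcomes)
    spare = sum(o.spare_seconds for o in outcomes)
    overtime = sum(o.overtime_seconds for o in outcomes)
    total_overtime_hours = overtime / 3600.0
    total_ochs = total_overtime_hours * overtime_rate
    n_unsucc = len(days) - n_succ
    return CohortOvertimeProfile(
        n_days=len(days),
        n_successful=n_succ,
        ssr=n_succ / len(days),
        total_spare_hours=spare / 3600.0,
        total_overtime_hours=total_overtime_hours,
        overtime_rate=overtime_rate,
        total_ochs_hours=total_ochs,
        ochs_per_unsuccessful_day=total_ochs / n_unsucc if n_unsucc else None,
        mean_spare_seconds_successful=spare / n_succ if n_succ else None,
    )


def _subset(days, subset, cutoff):
    if subset == "all":
        return list(days)
    if subset == "successful":
        return [d for d in days if classify_day(d, cutoff).successful]
    raise ValueError(f"unknown subset {subset!r}: expected 'all' or 'successful'")


def per_case_spread(
    days: list[DayRecord],
    subset: str = "all",
    cutoff: ClockTime = DEFAULT_CUTOFF,
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-case-number standard deviation of out-of-room times.

    Population SD (``ddof=0``) by default; at cohort sizes of hundreds of
    days the n vs n-1 choice moves the printed digits negligibly, but it is
    configurable.  Returns a frame indexed by case_number with ``sd_seconds``
    and an ``sd_hms`` display column.
    """
    sel = _subset(days, subset, cutoff)
    if len(sel) < 2:
        raise ValueError(f"per_case_spread needs >= 2 days in subset {subset!r}")
    mat = times_matrix(sel)
    sds = mat.std(axis=0, ddof=ddof)
    from fifthcase.schedule_io import format_duration

    return pd.DataFrame(
        {
            "case_number": [1, 2, 3, 4],
            "sd_seconds": sds,
            "sd_hms": [format_duration(s) for s in sds],
        }
    ).set_index("case_number")


def out_of_room_histogram(
    days: list[DayRecord],
    subset: str = "all",
    bin_width: int = 900,
    cutoff: ClockTime = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Binned counts of out-of-room times, keyed by case number.

    Bins are half-open ``[bin_start, bin_start + bin_width)`` aligned to
    midnight; every case of every selected day lands in exactly one bin, so
    per-case counts sum to the subset size under any bin width.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sel = _subset(days, subset, cutoff)
    mat = times_matrix(sel)
    from fifthcase.schedule_io import format_duration

    frames = []
    for k in range(4):
        starts = (mat[:, k] // bin_width).astype(int) * bin_width
        uniq, counts = np.unique(starts, return_counts=True)
        frames.append(
            pd.DataFrame(
                {
                    "case_number": k + 1,
                    "bin_start_seconds": uniq,
                    "bin_start": [format_duration(u) for u in uniq],
                    "count": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def plot_out_of_room_histogram(hist: pd.DataFrame, path, bin_width: int = 900) -> None:
    """Render the per-case out-of-room histogram to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    for case_no, grp in hist.groupby("case_number"):
        ax.bar(
            grp["bin_start_seconds"] / 3600.0,
            grp["count"],
            width=bin_width / 3600.0,
            align="edge",
            alpha=0.55,
            label=f"case {case_no}",
        )
    ax.set_xlabel("out-of-room time (hour of day)")
    ax.set_ylabel("days")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
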