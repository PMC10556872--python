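"""Clock times, day records, and the schedule CSV dialect.

The analysis consumes exactly one event per case: the *out-of-room* clock
time, the moment the patient leaves the operating room.  Times are integer
seconds since local midnight; the upper bound of 48 h leaves room for
pathological past-midnight overtime without wrapping.  A schedule CSV has
columns ``date`` (ISO-8601), ``case_no`` (1-4) and ``out_of_room``
(HH:MM:SS), four rows per day; an optional ``day_id`` column overrides the
default identifier (the ISO date string).
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: seconds in 48 hours — exclusive upper bound for any clock value
MAX_CLOCK_SECONDS = 172_800

_CLOCK_RE = re.compile(r"^(\d{1,2}):(\d{2})(?::(\d{2}))?$")

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri")


@dataclass(frozen=True, order=True)
class ClockTime:
    """A clock instant as integer seconds after local midnight."""

    seconds: int

    def __post_init__(self) -> None:
        if not isinstance(self.seconds, int):
            object.__setattr__(self, "seconds", int(round(self.seconds)))
        if not 0 <= self.seconds < MAX_CLOCK_SECONDS:
            raise ValueError(
                f"clock time {self.seconds} s outside [0, {MAX_CLOCK_SECONDS})"
            )

    @classmethod
    def parse(cls, text: str) -> "ClockTime":
        return parse_clock(text)

    @classmethod
    def from_hms(cls, hours: int, minutes: int = 0, seconds: int = 0) -> "ClockTime":
        return cls(hours * 3600 + minutes * 60 + seconds)

    def __str__(self) -> str:
        h, rem = divmod(self.seconds, 3600)
        m, s = divmod(rem, 60)
        return f"{h:02d}:{m:02d}:{s:02d}"

    def __add__(self, other: int) -> "ClockTime":
        return ClockTime(self.seconds + int(other))

    def __sub__(self, other: "ClockTime | int") -> int:
        if isinstance(other, ClockTime):
            return self.seconds - other.seconds
        return self.seconds - int(other)


def parse_clock(text: str) -> ClockTime:
    """Parse ``HH:MM:SS`` or ``HH:MM`` (hours 0-47) into a :class:`ClockTime`."""
    m = _CLOCK_RE.match(str(text).strip())
    if m is None:
        raise ValueError(f"malformed clock time {text!r}: expected HH:MM[:SS]")
    h, mi = int(m.group(1)), int(m.group(2))
    s = int(m.group(3)) if m.group(3) is not None else 0
    if h > 47:
        raise ValueError(f"malformed clock time {text!r}: hour field {h} > 47")
    if mi > 59:
        raise ValueError(f"malformed clock time {text!r}: minute field {mi} > 59")
    if s > 59:
        raise ValueError(f"malformed clock time {text!r}: second field {s} > 59")
    return ClockTime(h * 3600 + mi * 60 + s)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf."""
    import math

    return math.floor(x + 0.5)


def format_duration(seconds: float) -> str:
    """Render a duration as ``H:MM:SS`` (hours unpadded, may exceed 24)."""
    total = round_half_up(seconds)
    sign = "-" if total < 0 else ""
    total = abs(total)
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{sign}{h}:{m:02d}:{s:02d}"


@dataclass(frozen=True)
class CaseRecord:
    """One surgical case: its ordinal within the day and its out-of-room time."""

    day_id: str
    case_number: int
    out_of_room: ClockTime

    def __post_init__(self) -> None:
        if not 1 <= self.case_number <= 5:
            raise ValueError(f"case_number {self.case_number} outside 1..5")


@dataclass(frozen=True)
class DayRecord:
    """One OR day: exactly four observed cases with strictly increasing times.

    ``weekday`` is Mon-Fri; the room does not run weekends.  Wednesdays start
    30 minutes later than the usual 07:30 (education morning), which matters
    to the generator but not to classification: the success cutoff is the
    same clock instant on every weekday.
    """

    day_id: str
    date: _dt.date
    cases: tuple[CaseRecord, ...]
    weekday: str = field(default="")

    def __post_init__(self) -> None:
        if self.date.weekday() >= 5:
            raise ValueError(f"day {self.day_id}: {self.date} falls on a weekend")
        if not self.weekday:
            object.__setattr__(self, "weekday", WEEKDAY_NAMES[self.date.weekday()])
        if len(self.cases) != 4:
            raise ValueError(
                f"day {self.day_id}: expected exactly 4 cases, got {len(self.cases)}"
            )
        nums = [c.case_number for c in self.cases]
        if nums != [1, 2, 3, 4]:
            raise ValueError(f"day {self.day_id}: case numbers {nums} != [1, 2, 3, 4]")
        times = [c.out_of_room.seconds for c in self.cases]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"day {self.day_id}: out-of-room times {times} not strictly increasing"
            )

    @property
    def out_of_room_seconds(self) -> list[int]:
        return [c.out_of_room.seconds for c in self.cases]

    @property
    def fourth_out_of_room(self) -> ClockTime:
        return self.cases[3].out_of_room


def day_from_times(
    day_id: str, date: _dt.date, times: "list[ClockTime] | list[int]"
) -> DayRecord:
    """Build a 4-case :class:`DayRecord` from ordered out-of-room times."""
    clocks = [t if isinstance(t, ClockTime) else ClockTime(int(t)) for t in times]
    cases = tuple(
        CaseRecord(day_id=day_id, case_number=i + 1, out_of_room=t)
        for i, t in enumerate(clocks)
    )
    return DayRecord(day_id=day_id, date=date, cases=cases)


def read_schedule(path, *, on_invalid: str = "drop") -> list[DayRecord]:
    """Read a schedule CSV into validated :class:`DayRecord` objects.

    Days violating an invariant (wrong row count, duplicate or missing case
    numbers, non-monotone times, weekend dates) are dropped and logged with
    their ``day_id`` — never silently repaired.  Set ``on_invalid='raise'``
    to turn any rejection into an error.
    """
    days, rejections = read_schedule_detailed(path)
    if rejections and on_invalid == "raise":
        raise ValueError("invalid days in schedule: " + "; ".join(rejections))
    return days


def read_schedule_detailed(path) -> tuple[list[DayRecord], list[str]]:
    """Like :func:`read_schedule` but also returns rejection messages."""
    df = pd.read_csv(path, dtype=str)
    required = {"date", "case_no", "out_of_room"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule CSV missing column(s): {sorted(missing)}")

    days: list[DayRecord] = []
    rejections: list[str] = []
    key = "day_id" if "day_id" in df.columns else "date"
    for day_key, grp in df.groupby(key, sort=True):
        day_id = str(day_key)
        try:
            date = _dt.date.fromisoformat(str(grp["date"].iloc[0]))
            if len(grp) != 4:
                raise ValueError(
                    f"day {day_id}: expected 4 rows, got {len(grp)}"
                )
            grp = grp.assign(_no=grp["case_no"].astype(int)).sort_values("_no")
            cases = tuple(
                CaseRecord(
                    day_id=day_id,
                    case_number=int(row["_no"]),
                    out_of_room=parse_clock(row["out_of_room"]),
                )
                for _, row in grp.iterrows()
            )
            days.append(DayRecord(day_id=day_id, date=date, cases=cases))
        except ValueError as exc:
            rejections.append(f"{day_id}: {exc}")
    logger.info(
        "read_schedule: accepted %d day(s), rejected %d", len(days), len(rejections)
    )
    for msg in rejections:
        logger.warning("rejected day %s", msg)
    return days, rejections


def write_schedule(days: "list[DayRecord]", path) -> None:
    """Write DayRecords as a schedule CSV; round-trips bit-exactly."""
    rows = [
        {
            "day_id": d.day_id,
            "date": d.date.isoformat(),
            "weekday": d.weekday,
            "case_no": c.case_number,
            "out_of_room": str(c.out_of_room),
        }
        for d in days
        for c in d.cases
    ]
    pd.DataFrame(
        rows, columns=["day_id", "date", "weekday", "case_no", "out_of_room"]
    ).to_csv(path, index=False)


def times_matrix(days: "list[DayRecord]"):
    """Out-of-room times as an (n_days, 4) float array of seconds."""
    import numpy as np

    return np.array([d.out_of_room_seconds for d in days], dtype=float).reshape(
        len(days), 4
    )
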