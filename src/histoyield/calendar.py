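"""8-day composite calendar arithmetic.

Satellite composites are anchored on a fixed day-of-year grid
{1, 9, 17, ..., 361} regardless of leap years (the MODIS convention:
46 periods per year, the last one truncated at Dec 31).  A seasonal
calendar keeps the periods whose *start date* falls inside a season
window; for a season of Apr 1 - Dec 31 that is exactly 34 periods
(start DOYs 97..361).  In-season forecasting truncates tensors at a
"time node" — a calendar date on the composite grid — so JUN-2 keeps
8 periods, AUG-21 keeps 18, DEC-27 keeps all 34.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

__all__ = [
    "COMPOSITE_START_DOYS",
    "CompositeCalendar",
    "TimeNode",
    "composite_calendar",
    "truncate_calendar",
    "default_time_nodes",
    "doy",
]

#: fixed composite start grid: 1, 9, ..., 361
COMPOSITE_START_DOYS: tuple[int, ...] = tuple(range(1, 362, 8))


def doy(year: int, month: int, day: int) -> int:
    """Day of year of a calendar date."""
    return _dt.date(year, month, day).timetuple().tm_yday


def _days_in_year(year: int) -> int:
    return 366 if _dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365


@dataclass(frozen=True)
class CompositeCalendar:
    """Ordered 8-day composite windows of one season of one year.

    ``periods`` holds (start_doy, end_doy) pairs, both inclusive; the last
    window of the year is clipped at Dec 31.
    """

    year: int
    periods: tuple[tuple[int, int], ...]
    season: tuple[str, str]  # ISO "MM-DD" season start/end

    def __post_init__(self) -> None:
        starts = [p[0] for p in self.periods]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("calendar periods must be strictly increasing")

    def __len__(self) -> int:
        return len(self.periods)

    @property
    def start_doys(self) -> tuple[int, ...]:
        return tuple(p[0] for p in self.periods)

    def period_dates(self) -> list[_dt.date]:
        """Start date of each period."""
        base = _dt.date(self.year, 1, 1)
        return [base + _dt.timedelta(days=s - 1) for s in self.start_doys]

    def step_of_date(self, month: int, day: int) -> int:
        """1-based index of the last period starting on or before a date."""
        d = doy(self.year, month, day)
        steps = [i for i, s in enumerate(self.start_doys, 1) if s <= d]
        if not steps:
            raise ValueError(f"date {month:02d}-{day:02d} precedes the first period")
        return steps[-1]


def composite_calendar(
    year: int,
    season_start: tuple[int, int] = (4, 1),
    season_end: tuple[int, int] = (12, 31),
) -> CompositeCalendar:
    """All fixed-grid 8-day periods whose start date lies in the season.

    Parameters are (month, day) pairs.  Raises if the window is inverted.
    """
    start = _dt.date(year, *season_start)
    end = _dt.date(year, *season_end)
    if end < start:
        raise ValueError(f"inverted season window {start} .. {end}")
    lo, hi = start.timetuple().tm_yday, end.timetuple().tm_yday
    last = _days_in_year(year)
    periods = tuple(
        (s, min(s + 7, last)) for s in COMPOSITE_START_DOYS if lo <= s <= hi
    )
    return CompositeCalendar(
        year=year,
        periods=periods,
        season=(f"{season_start[0]:02d}-{season_start[1]:02d}", f"{season_end[0]:02d}-{season_end[1]:02d}"),
    )


def truncate_calendar(calendar: CompositeCalendar, month: int, day: int) -> CompositeCalendar:
    """Restrict a calendar to periods starting on or before the node date."""
    cutoff = doy(calendar.year, month, day)
    periods = tuple(p for p in calendar.periods if p[0] <= cutoff)
    if not periods:
        raise ValueError(f"time node {month:02d}-{day:02d} precedes the first period")
    return CompositeCalendar(calendar.year, periods, (calendar.season[0], f"{month:02d}-{day:02d}"))


@dataclass(frozen=True)
class TimeNode:
    """A forecast date on the composite grid, e.g. AUG-21."""

    label: str
    month: int
    day: int

    def step_index(self, calendar: CompositeCalendar) -> int:
        return calendar.step_of_date(self.month, self.day)


_DEFAULT_NODES = (
    ("JUN-2", 6, 2),
    ("JUL-4", 7, 4),
    ("AUG-5", 8, 5),
    ("AUG-13", 8, 13),
    ("AUG-21", 8, 21),
    ("AUG-29", 8, 29),
    ("SEP-14", 9, 14),
    ("OCT-16", 10, 16),
    ("NOV-17", 11, 17),
    ("DEC-27", 12, 27),
)


def default_time_nodes() -> list[TimeNode]:
    """The standard in-season forecast dates (JUN-2 ... DEC-27)."""
    return [TimeNode(lbl, m, d) for lbl, m, d in _DEFAULT_NODES]
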