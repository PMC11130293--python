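"""Calendar-week conventions used throughout the pipeline.

Weeks are Monday-start calendar weeks. Week indices are counted from the
week containing the study start date (index 0), so indexing is contiguous
over the study window even when the window does not begin on a Monday.

The pre-shock reference ("baseline") week is the second Monday-start week
fully contained in March of the study year -- the week before the return to
school in Chile, when most devices are back at their primary residence.
The long-term relocation call compares this baseline against the statistical
mode of the weekly home over the four Monday-start weeks fully contained in
November.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

__all__ = [
    "monday_on_or_before",
    "week_index",
    "week_start_date",
    "n_study_weeks",
    "baseline_week_index",
    "november_week_indices",
    "week_dates",
]


def monday_on_or_before(day: dt.date) -> dt.date:
    """Monday of the calendar week containing *day*."""
    return day - dt.timedelta(days=day.weekday())


def week_index(dates, study_start: dt.date):
    """Week index (0-based, Monday-start) of *dates* relative to the study start.

    Accepts a single date or any array-like accepted by ``pd.to_datetime``.
    """
    week0 = monday_on_or_before(study_start)
    if isinstance(dates, (dt.date, dt.datetime, pd.Timestamp)):
        d = pd.Timestamp(dates).date()
        return (d - week0).days // 7
    days = (pd.to_datetime(dates).values.astype("datetime64[D]")
            - np.datetime64(week0, "D")).astype(np.int64)
    return days // 7


def week_start_date(index: int, study_start: dt.date) -> dt.date:
    """Monday beginning week *index* of the study window."""
    return monday_on_or_before(study_start) + dt.timedelta(weeks=int(index))


def n_study_weeks(study_start: dt.date, study_end: dt.date) -> int:
    """Number of week indices spanned by the inclusive study window."""
    return int(week_index(study_end, study_start)) + 1


def _mondays_fully_inside(year: int, month: int) -> list[dt.date]:
    first = dt.date(year, month, 1)
    last = (first + dt.timedelta(days=40)).replace(day=1) - dt.timedelta(days=1)
    m = first if first.weekday() == 0 else first + dt.timedelta(days=7 - first.weekday())
    out = []
    while m + dt.timedelta(days=6) <= last:
        out.append(m)
        m += dt.timedelta(days=7)
    return out


def baseline_week_index(study_start: dt.date) -> int:
    """Index of the second Monday-start week fully inside March of the study year."""
    mondays = _mondays_fully_inside(study_start.year, 3)
    if len(mondays) < 2:
        raise ValueError("March has fewer than two full Monday-start weeks")
    return int(week_index(mondays[1], study_start))


def november_week_indices(study_start: dt.date) -> list[int]:
    """Indices of the (four) Monday-start weeks fully inside November."""
    return [int(week_index(m, study_start)) for m in
            _mondays_fully_inside(study_start.year, 11)]


def week_dates(index: int, study_start: dt.date) -> pd.DatetimeIndex:
    """The seven calendar dates of week *index*."""
    start = week_start_date(index, study_start)
    return pd.date_range(start, periods=7, freq="D")
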