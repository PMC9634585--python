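"""Calendar/day arithmetic used throughout the package.

Dates are handled internally as proleptic-Gregorian ordinal day numbers
(``datetime.date.toordinal``); intervals are half-open ``[start, end)`` in
whole days, and person-time is converted with 365.25 days per year.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25


def to_day(d) -> int:
    """Convert a date-like (date, Timestamp, ISO string) to an ordinal day."""
    if isinstance(d, (int, np.integer)):
        return int(d)
    if isinstance(d, str):
        d = dt.date.fromisoformat(d)
    if isinstance(d, pd.Timestamp):
        d = d.date()
    if isinstance(d, dt.datetime):
        d = d.date()
    if not isinstance(d, dt.date):
        raise TypeError(f"not a date: {d!r}")
    return d.toordinal()


def from_day(n: int) -> dt.date:
    return dt.date.fromordinal(int(n))


def days_to_years(days) -> float:
    return days / DAYS_PER_YEAR


def years_to_days(years: float) -> int:
    """Round a duration in years to the nearest whole day."""
    return int(round(years * DAYS_PER_YEAR))


def add_years(d: dt.date, years: int) -> dt.date:
    """Calendar birthday `years` after `d`; Feb 29 maps to Feb 28."""
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # Feb 29 in a non-leap target year
        return d.replace(year=d.year + years, day=28)


def dates_to_days(series: pd.Series) -> np.ndarray:
    """Vectorised date-column → ordinal days; missing → -1.

    Uses numpy datetime64[D] (not nanosecond timestamps) so that dates far
    outside 1677–2262 — e.g. a simulated emigration centuries ahead — parse.
    """
    s = pd.Series(series)
    cleaned = [
        None
        if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NaT or v == ""
        else (v.date() if isinstance(v, (pd.Timestamp, dt.datetime)) else v)
        for v in s
    ]
    arr = np.array(cleaned, dtype="datetime64[D]")
    # days since 1970-01-01, shifted to proleptic ordinal (1970-01-01 = 719163)
    ints = arr.astype(np.int64) + 719163
    return np.where(np.isnat(arr), -1, ints)
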