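"""Integer-day date arithmetic.

All dates inside the pipeline are integers counting days since 1970-01-01
(the numpy/pandas epoch).  Intervals are half-open ``[start, end)``; a
"last day" printed in output is ``end - 1``.  Calendar (ISO-8601) rendering
happens only at the I/O boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25


def to_day(value) -> int:
    """Convert an ISO date string / date-like to integer days since epoch."""
    ts = pd.Timestamp(value)
    return int((ts - pd.Timestamp("1970-01-01")).days)


def to_iso(day: int) -> str:
    """Render an integer epoch day as an ISO-8601 date string."""
    return str((pd.Timestamp("1970-01-01") + pd.Timedelta(days=int(day))).date())


def series_to_days(s: pd.Series, *, context: str = "date") -> pd.Series:
    """Parse a column of ISO dates to integer days, naming bad rows.

    Raises ``ValueError`` listing the 0-based row positions of unparseable
    entries.  Missing values (empty string / NaN) become pandas ``NA``.
    """
    raw = s.replace("", pd.NA)
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = raw.notna() & parsed.isna()
    if bad.any():
        rows = [int(i) for i in np.flatnonzero(bad.to_numpy())[:10]]
        raise ValueError(f"unparseable {context} in rows {rows}: "
                         f"{s[bad].head(3).tolist()}")
    days = (parsed - pd.Timestamp("1970-01-01")).dt.days
    return days.astype("Int64")


def days_to_iso_series(s: pd.Series) -> pd.Series:
    """Render an integer-day column as ISO strings (NA-safe)."""
    as_float = pd.to_numeric(s, errors="coerce").astype(float)
    out = pd.to_datetime(as_float, unit="D").dt.strftime("%Y-%m-%d")
    return out.where(s.notna(), "")


def years_between(start_day, end_day) -> float:
    """Elapsed time in (mean Julian) years between two epoch days."""
    return (end_day - start_day) / DAYS_PER_YEAR
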