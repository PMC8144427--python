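"""Calendar <-> model-time conversion.

Model time ``t`` is measured in years on a fixed 365-day calendar with
``t = 0`` at March 1, the seasonal trough of 25OHD in the northern
hemisphere (phase ``nu = pi`` in the status curves).  Weeks are converted
at 365/7 weeks per year everywhere.
"""

from __future__ import annotations

DAYS_PER_YEAR = 365
WEEKS_PER_YEAR = DAYS_PER_YEAR / 7.0

# cumulative day-of-year at the start of each month, fixed 365-day year
_MONTH_LENGTHS = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
_CUM_DAYS = [0]
for _m in _MONTH_LENGTHS:
    _CUM_DAYS.append(_CUM_DAYS[-1] + _m)

_MONTH_NAMES = {
    name.lower(): i + 1
    for i, name in enumerate(
        ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
         "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
    )
}

_MARCH1_DOY = _CUM_DAYS[2]  # day-of-year index of March 1 (0-based)


def parse_month_day(date: "str | tuple[int, int]") -> tuple[int, int]:
    """Parse a calendar day given as ``(month, day)``, ``"MM-DD"`` or ``"Sep 1"``."""
    if isinstance(date, tuple):
        month, day = int(date[0]), int(date[1])
    else:
        text = date.strip()
        if "-" in text:
            m_str, d_str = text.split("-")
            month, day = int(m_str), int(d_str)
        else:
            parts = text.split()
            month = _MONTH_NAMES[parts[0][:3].lower()]
            day = int(parts[1]) if len(parts) > 1 else 1
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    if not 1 <= day <= _MONTH_LENGTHS[month - 1]:
        raise ValueError(f"day out of range for month {month}: {day}")
    return month, day


def date_to_t(date: "str | tuple[int, int]") -> float:
    """Model time in [0, 1) of a calendar day (t=0 is March 1)."""
    month, day = parse_month_day(date)
    doy = _CUM_DAYS[month - 1] + (day - 1)
    return ((doy - _MARCH1_DOY) % DAYS_PER_YEAR) / DAYS_PER_YEAR


def date_to_t_end(date: "str | tuple[int, int]") -> float:
    """Model time in (0, 1] of the *end* of a calendar day (inclusive ranges)."""
    month, day = parse_month_day(date)
    doy = _CUM_DAYS[month - 1] + day  # end of the day
    t = ((doy - _MARCH1_DOY) % DAYS_PER_YEAR) / DAYS_PER_YEAR
    return t if t > 0 else 1.0


def weeks_to_years(weeks: float) -> float:
    return weeks / WEEKS_PER_YEAR
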