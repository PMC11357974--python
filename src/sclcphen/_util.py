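"""Shared numeric/display helpers.

Display rounding is done on exact integer ratios through ``decimal`` so that
half cases (e.g. 92/320 = 0.2875) round half-up the way published tables do;
rounding a binary float first would silently round some of them down.
"""

from __future__ import annotations

from decimal import ROUND_CEILING, ROUND_FLOOR, ROUND_HALF_UP, Decimal

import pandas as pd


def ratio_display(num: int, den: int, places: int = 3) -> str:
    """``num/den`` rounded half-up to *places* decimals, as a string.

    Returns ``""`` when the denominator is zero (undefined metric).
    """
    if den == 0:
        return ""
    q = Decimal(1).scaleb(-places)
    return str((Decimal(int(num)) / Decimal(int(den))).quantize(q, rounding=ROUND_HALF_UP))


def percent_display(num: int, den: int) -> str:
    """Whole-percent display (half-up), e.g. 1251/1315 -> ``"95%"``."""
    if den == 0:
        return ""
    val = (Decimal(int(num)) * 100 / Decimal(int(den))).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return f"{val}%"


def bound_upper(num: int, den: int, places: int = 2) -> str:
    """``"< b"`` with b = num/den rounded *up* to *places* decimals."""
    q = Decimal(1).scaleb(-places)
    b = (Decimal(int(num)) / Decimal(int(den))).quantize(q, rounding=ROUND_CEILING)
    return f"< {b}"


def bound_lower(num: int, den: int, places: int = 2) -> str:
    """``"> b"`` with b = 1 - num/den rounded *down* to *places* decimals."""
    q = Decimal(1).scaleb(-places)
    b = (1 - Decimal(int(num)) / Decimal(int(den))).quantize(q, rounding=ROUND_FLOOR)
    return f"> {b}"


def month_index(dates) -> pd.Series:
    """Integer month index (year*12 + month-1) of a datetime-like Series."""
    dates = pd.to_datetime(dates)
    return dates.dt.year * 12 + (dates.dt.month - 1)


def month_index_of_period(months: pd.Series) -> pd.Series:
    """Integer month index of a 'YYYY-MM' string Series."""
    p = pd.PeriodIndex(months.astype(str), freq="M")
    return pd.Series(p.year * 12 + (p.month - 1), index=months.index)


def month_start(index: pd.Series | int):
    """Timestamp of the first day of an integer month index."""
    if isinstance(index, int):
        return pd.Timestamp(year=index // 12, month=index % 12 + 1, day=1)
    parts = pd.DataFrame({"year": index // 12, "month": index % 12 + 1})
    parts["day"] = 1
    return pd.to_datetime(parts)
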