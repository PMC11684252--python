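"""Independent brute-force oracles, kept free of the package's interval logic."""

import datetime as dt


def daily_stock_covered_days(fills, index_date: dt.date, end_date: dt.date) -> int:
    """Day-by-day 'pills on hand' simulation.

    Stock is incremented by days_supply on each fill date and decremented by
    one on every day it is positive; a day is covered iff stock was positive.
    Supply remaining at the window end is discarded (truncation).
    """
    supply = {}
    for fill_date, days_supply in fills:
        supply[fill_date] = supply.get(fill_date, 0) + days_supply
    stock = 0
    covered = 0
    day = index_date
    one = dt.timedelta(days=1)
    while day <= end_date:
        stock += supply.get(day, 0)
        if stock > 0:
            covered += 1
            stock -= 1
        day += one
    return covered


def enumerate_covered_dates(spans) -> set:
    """All dates covered by a collection of (start, end) closed intervals."""
    out = set()
    one = dt.timedelta(days=1)
    for start, end in spans:
        day = start
        while day <= end:
            out.add(day)
            day += one
    return out
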