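"""Independent brute-force reference implementations.

Deliberately naive and written without reference to the package internals:
plain loops, set membership, and the textbook chi-square cell sum.  Tests
compare the package against these on random inputs.
"""

from __future__ import annotations

import datetime as dt
from typing import Sequence


def oracle_sequence(records) -> tuple[int, int]:
    """(out_of_order_count, unique_arrived_date_count) by exhaustive pair scan."""
    out = 0
    for x in records:
        for y in records:
            if (y.scheduled_on < x.scheduled_on
                    and y.arrived_on > x.arrived_on):
                out += 1
                break
    dates = {r.arrived_on for r in records}
    return out, len(dates)


def oracle_action_date(r) -> dt.date:
    if r.rescheduled_on is not None:
        return r.rescheduled_on
    if r.canceled_on is not None:
        return r.canceled_on
    return r.scheduled_for


def oracle_resolution(nonarrived, check_dates: set) -> int:
    """Unresolved count by direct set membership."""
    return sum(1 for r in nonarrived if oracle_action_date(r) not in check_dates)


def oracle_location(arrived, all_dates_denominator: bool) -> tuple[int, int]:
    """(multi_location_date_count, denominator) by date grouping."""
    days: dict[dt.date, list] = {}
    for r in arrived:
        days.setdefault(r.arrived_on, []).append(" ".join(r.location.split()))
    numer = sum(1 for locs in days.values() if len(set(locs)) >= 2)
    if all_dates_denominator:
        denom = len(days)
    else:
        denom = sum(1 for locs in days.values() if len(locs) >= 2)
    return numer, denom


def oracle_harmonic(values: Sequence[float]) -> float:
    if any(v == 0 for v in values):
        return 0.0
    return len(values) / sum(1.0 / v for v in values)


def oracle_chi_square(table) -> tuple[float, int]:
    """(statistic, df) by the cell-by-cell (O-E)^2/E sum."""
    rows = [list(map(float, row)) for row in table]
    total = sum(sum(r) for r in rows)
    row_sums = [sum(r) for r in rows]
    col_sums = [sum(rows[i][j] for i in range(len(rows)))
                for j in range(len(rows[0]))]
    stat = 0.0
    for i, r in enumerate(rows):
        for j, obs in enumerate(r):
            exp = row_sums[i] * col_sums[j] / total
            stat += (obs - exp) ** 2 / exp
    df = (len(rows) - 1) * (len(rows[0]) - 1)
    return stat, df
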