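"""Scheduling-complexity components and their harmonic-mean composite.

Three per-patient fractions summarise distinct sources of scheduling
disruption over a (typically one-year) window of appointment records:

sequence complexity
    How often appointments were booked and attended out of first-in
    first-out order.  An arrived appointment is *out of order* when some
    other appointment was booked strictly earlier yet attended strictly
    later.  The fraction is the count of such appointments over the number
    of distinct attended dates — numerator in appointments, denominator in
    dates, deliberately kept as published, so values above 1 are possible
    when several same-date appointments are each out of order.

resolution complexity
    The fraction of non-arrived appointments (rescheduled, canceled, or
    no-show) whose action date does not co-occur with any other scheduling
    action, i.e. disruptions left dangling rather than folded into a
    rebooking or another care event.

location complexity
    The proportion of attended dates on which care spanned two or more
    distinct locations (full facility + floor string).

The composite *scheduling complexity* is the harmonic mean of the three,
with the convention that it is 0 whenever any component is 0.  Equal
weights are intentional; the harmonic mean makes the composite small
unless all three disruption sources are present.

Two published phrasings of the algorithm disagree on details; both are
supported via :class:`ComplexityConfig`.  The defaults follow the prose
definitions (resolution checked against all action dates; location
denominator = all arrived dates); the literal pseudocode variants
(arrived dates only; multi-appointment dates only) are selectable.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    AppointmentRecord,
    PatientSchedule,
    action_date,
    partition,
)

__all__ = [
    "ResolutionCheckSet",
    "LocationDenominator",
    "ComplexityConfig",
    "ComplexityProfile",
    "sequence_complexity",
    "resolution_complexity",
    "resolution_check_dates",
    "location_complexity",
    "harmonic_mean",
    "scheduling_complexity",
]


class ResolutionCheckSet(enum.Enum):
    """Which dates count as resolving a non-arrived appointment's action.

    ALL_ACTION_DATES: arrived dates plus the booking (scheduled_on) dates of
    the patient's other appointments — a reschedule whose replacement was
    booked on the bump date is resolved.  ARRIVED_ONLY: arrived dates only,
    the literal pseudocode check.
    """

    ALL_ACTION_DATES = "all_action_dates"
    ARRIVED_ONLY = "arrived_only"


class LocationDenominator(enum.Enum):
    """Denominator for location complexity.

    ALL_ARRIVED_DATES: every distinct attended date.  MULTI_AID_DATES: only
    attended dates with two or more appointments (the literal pseudocode
    denominator).
    """

    ALL_ARRIVED_DATES = "all_arrived_dates"
    MULTI_AID_DATES = "multi_aid_dates"


@dataclass(frozen=True)
class ComplexityConfig:
    """Variant switches for the complexity computation.

    Defaults follow the prose definitions of the metric; the alternative
    members reproduce the published pseudocode literally.  Date comparisons
    are always strict (same-day ties never create out-of-order flags) and a
    zero component always zeroes the composite.
    """

    resolution_check_set: ResolutionCheckSet = ResolutionCheckSet.ALL_ACTION_DATES
    location_denominator: LocationDenominator = LocationDenominator.ALL_ARRIVED_DATES

    def to_dict(self) -> dict:
        return {
            "resolution_check_set": self.resolution_check_set.value,
            "location_denominator": self.location_denominator.value,
            "zero_component_policy": "composite_zero",
            "strict_date_comparison": True,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComplexityConfig":
        return cls(
            resolution_check_set=ResolutionCheckSet(
                d.get("resolution_check_set", "all_action_dates")
            ),
            location_denominator=LocationDenominator(
                d.get("location_denominator", "all_arrived_dates")
            ),
        )


DEFAULT_CONFIG = ComplexityConfig()

#: Literal rendering of the published pseudocode.
LITERAL_CONFIG = ComplexityConfig(
    resolution_check_set=ResolutionCheckSet.ARRIVED_ONLY,
    location_denominator=LocationDenominator.MULTI_AID_DATES,
)


@dataclass(frozen=True)
class ComplexityProfile:
    """Per-patient complexity components, composite, and intermediate counts."""

    patient_id: str
    sequence_complexity: float
    resolution_complexity: float
    location_complexity: float
    scheduling_complexity: float
    out_of_order_count: int
    unresolved_count: int
    multi_location_date_count: int
    unique_arrived_date_count: int
    nonarrived_count: int

    FIELDS = (
        "patient_id",
        "sequence_complexity",
        "resolution_complexity",
        "location_complexity",
        "scheduling_complexity",
        "out_of_order_count",
        "unresolved_count",
        "multi_location_date_count",
        "unique_arrived_date_count",
        "nonarrived_count",
    )

    def as_row(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}


def sequence_complexity(
    arrived: Sequence[AppointmentRecord],
) -> tuple[float, int, int]:
    """Out-of-order fraction of the arrived set.

    Returns ``(fraction, out_of_order_count, unique_arrived_date_count)``.
    An arrived appointment x is out of order iff some arrived appointment y
    was booked strictly before x (scheduled_on) and attended strictly after
    x (arrived_on).  The denominator is the number of distinct arrived
    dates; an empty arrived set yields 0 by convention.
    """
    if not arrived:
        return 0.0, 0, 0
    sched = np.array([r.scheduled_on.toordinal() for r in arrived])
    arr = np.array([r.arrived_on.toordinal() for r in arrived])
    # x out-of-order iff any y with sched[y] < sched[x] and arr[y] > arr[x]
    flags = ((sched[None, :] < sched[:, None]) & (arr[None, :] > arr[:, None])).any(
        axis=1
    )
    out_of_order = int(flags.sum())
    n_dates = int(np.unique(arr).size)
    return out_of_order / n_dates, out_of_order, n_dates


def resolution_check_dates(
    schedule: PatientSchedule,
    arrived: Sequence[AppointmentRecord],
    config: ComplexityConfig = DEFAULT_CONFIG,
) -> set[dt.date]:
    """Build the set of dates against which action dates are checked.

    Always includes every arrived date; under ALL_ACTION_DATES also the
    scheduled_on (booking) dates of all of the patient's appointments, so
    that e.g. a bump date coinciding with the replacement's booking counts
    as resolved.
    """
    dates = {r.arrived_on for r in arrived if r.arrived_on is not None}
    if config.resolution_check_set is ResolutionCheckSet.ALL_ACTION_DATES:
        dates.update(r.scheduled_on for r in schedule.records)
    return dates


def resolution_complexity(
    nonarrived: Sequence[AppointmentRecord],
    check_dates: set[dt.date],
) -> tuple[float, int]:
    """Unresolved fraction of the non-arrived set.

    A non-arrived appointment is unresolved iff its action date (cancel
    date, bump date, or scheduled date for a no-show) is not in
    ``check_dates``.  Returns ``(fraction, unresolved_count)``; an empty
    non-arrived set yields 0 by convention.
    """
    if not nonarrived:
        return 0.0, 0
    unresolved = sum(1 for r in nonarrived if action_date(r) not in check_dates)
    return unresolved / len(nonarrived), unresolved


def _normalize_location(loc: str) -> str:
    # exact match after trimming and collapsing internal whitespace; case kept
    return " ".join(loc.split())


def location_complexity(
    arrived: Sequence[AppointmentRecord],
    config: ComplexityConfig = DEFAULT_CONFIG,
) -> tuple[float, int]:
    """Multi-location fraction of attended dates.

    Numerator: distinct arrived dates whose appointments span >= 2 distinct
    locations.  Denominator: all distinct arrived dates, or only those with
    >= 2 appointments under MULTI_AID_DATES.  Returns
    ``(fraction, multi_location_date_count)``; empty denominator yields 0.
    """
    by_date: dict[dt.date, set[str]] = {}
    counts: dict[dt.date, int] = {}
    for r in arrived:
        by_date.setdefault(r.arrived_on, set()).add(_normalize_location(r.location))
        counts[r.arrived_on] = counts.get(r.arrived_on, 0) + 1
    multi_loc = sum(1 for locs in by_date.values() if len(locs) >= 2)
    if config.location_denominator is LocationDenominator.ALL_ARRIVED_DATES:
        denom = len(by_date)
    else:
        denom = sum(1 for n in counts.values() if n >= 2)
    if denom == 0:
        return 0.0, multi_loc
    return multi_loc / denom, multi_loc


def harmonic_mean(components: Sequence[float]) -> float:
    """Harmonic mean with the zero convention.

    ``n / sum(1/c)`` when every component is positive; 0 if any component
    is 0.  Negative components or an empty list are contract violations.
    """
    if len(components) == 0:
        raise ValueError("harmonic_mean of an empty list is undefined")
    if any(c < 0 for c in components):
        raise ValueError("harmonic_mean requires non-negative components")
    if any(c == 0 for c in components):
        return 0.0
    return len(components) / sum(1.0 / c for c in components)


def scheduling_complexity(
    schedule: PatientSchedule,
    config: ComplexityConfig = DEFAULT_CONFIG,
    as_of: Optional[dt.date] = None,
) -> ComplexityProfile:
    """Full per-patient complexity profile.

    Partitions the (already window-filtered) schedule into arrived and
    non-arrived appointments, computes the three components, and aggregates
    them by harmonic mean.  ``as_of`` defaults to the day after the latest
    date in the record set, which closes every appointment in a completed
    window.  Degenerate schedules produce all-zero components.
    """
    if as_of is None:
        latest = schedule.latest_date()
        as_of = (latest + dt.timedelta(days=1)) if latest else dt.date.today()
    arrived, nonarrived = partition(schedule, as_of)
    seq, ooo, n_dates = sequence_complexity(arrived)
    check = resolution_check_dates(schedule, arrived, config)
    res, unresolved = resolution_complexity(nonarrived, check)
    loc, multi = location_complexity(arrived, config)
    composite = harmonic_mean([seq, res, loc])
    return ComplexityProfile(
        patient_id=schedule.patient_id,
        sequence_complexity=seq,
        resolution_complexity=res,
        location_complexity=loc,
        scheduling_complexity=composite,
        out_of_order_count=ooo,
        unresolved_count=unresolved,
        multi_location_date_count=multi,
        unique_arrived_date_count=n_dates,
        nonarrived_count=len(nonarrived),
    )
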