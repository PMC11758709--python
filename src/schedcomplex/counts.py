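"""Count-based outcome ratios and the count-based adjustment composite.

These are the first-order comparator metrics: per patient, the fraction of
appointments with each terminal outcome, and a composite "count-based
adjustment" defined as the harmonic mean of the rescheduled, canceled, and
no-show ratios (zero convention as for scheduling complexity, so a patient
with no disruptions of any one kind gets adjustment 0).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Optional

from .complexity import harmonic_mean
from .model import Outcome, PatientSchedule, classify_outcome


@dataclass(frozen=True)
class CountRatios:
    """Per-patient outcome fractions over non-pending appointments."""

    patient_id: str
    total_aids: int
    arrived_ratio: float
    nonarrived_ratio: float
    rescheduled_ratio: float
    canceled_ratio: float
    no_show_ratio: float
    count_based_adjustment: float

    FIELDS = (
        "patient_id",
        "total_aids",
        "arrived_ratio",
        "nonarrived_ratio",
        "rescheduled_ratio",
        "canceled_ratio",
        "no_show_ratio",
        "count_based_adjustment",
    )

    def as_row(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}


def count_based_adjustment(
    rescheduled_ratio: float, canceled_ratio: float, no_show_ratio: float
) -> float:
    """Harmonic mean of the three disruption ratios (0 if any ratio is 0)."""
    return harmonic_mean([rescheduled_ratio, canceled_ratio, no_show_ratio])


def outcome_ratios(
    schedule: PatientSchedule, as_of: Optional[dt.date] = None
) -> CountRatios:
    """Outcome counts over unique appointments, as fractions.

    Each non-pending appointment contributes once; the denominator is the
    number of non-pending appointments.  ``as_of`` defaults to the day
    after the latest date in the record set.  A schedule with zero
    non-pending appointments yields all-zero ratios with a warning.
    """
    if as_of is None:
        latest = schedule.latest_date()
        as_of = (latest + dt.timedelta(days=1)) if latest else dt.date.today()
    tallies = {o: 0 for o in Outcome}
    for r in schedule.records:
        tallies[classify_outcome(r, as_of)] += 1
    total = len(schedule.records) - tallies[Outcome.PENDING]
    if total == 0:
        warnings.warn(
            f"patient {schedule.patient_id!r}: no closed appointments; "
            "ratios reported as 0",
            stacklevel=2,
        )
        return CountRatios(schedule.patient_id, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    resched = tallies[Outcome.RESCHEDULED] / total
    cancel = tallies[Outcome.CANCELED] / total
    no_show = tallies[Outcome.NO_SHOW] / total
    arrived = tallies[Outcome.ARRIVED] / total
    return CountRatios(
        patient_id=schedule.patient_id,
        total_aids=total,
        arrived_ratio=arrived,
        nonarrived_ratio=resched + cancel + no_show,
        rescheduled_ratio=resched,
        canceled_ratio=cancel,
        no_show_ratio=no_show,
        count_based_adjustment=count_based_adjustment(resched, cancel, no_show),
    )
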