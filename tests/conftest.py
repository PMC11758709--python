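"""Shared fixtures: the worked single-patient example and random schedules."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from schedcomplex import AppointmentRecord, PatientSchedule


def _d(month: int, day: int) -> dt.date:
    return dt.date(2023, month, day)


# The canonical 12-appointment example patient: one year of mixed outcomes,
# a reschedule chain (VID-6), a serial daily treatment block (VID-7), and a
# same-day two-location imaging pair on 1/15.
EXAMPLE_ROWS = [
    ("VID-1", "AID-1", "New consult", "Hospital A - 2nd FL",
     _d(1, 1), _d(1, 5), None, None, _d(1, 5)),
    ("VID-1", "AID-2", "Colon screening", "Hospital B - Ground",
     _d(1, 1), _d(2, 1), _d(1, 17), None, None),
    ("VID-2", "AID-3", "Skin check", "Hospital B - Ground",
     _d(1, 3), _d(1, 10), None, None, _d(1, 10)),
    ("VID-3", "AID-4", "Echocardiogram", "Hospital A - Ground",
     _d(1, 5), _d(1, 20), None, None, _d(1, 20)),
    ("VID-4", "AID-5", "MRI", "Hospital A - Ground",
     _d(1, 10), _d(1, 15), None, None, _d(1, 15)),
    ("VID-5", "AID-6", "Mammogram", "Hospital A - 2nd FL",
     _d(1, 15), _d(1, 15), None, None, _d(1, 15)),
    ("VID-6", "AID-7", "Follow up", "Hospital A - 2nd FL",
     _d(2, 1), _d(2, 20), None, _d(2, 10), None),
    ("VID-6", "AID-8", "Follow up", "Hospital A - 2nd FL",
     _d(2, 10), _d(2, 25), None, None, _d(2, 25)),
    ("VID-7", "AID-9", "Treatment", "Infusion center - 2nd FL",
     _d(4, 1), _d(4, 5), None, None, _d(4, 5)),
    ("VID-7", "AID-10", "Treatment", "Infusion center - 2nd FL",
     _d(4, 1), _d(4, 6), None, None, _d(4, 6)),
    ("VID-7", "AID-11", "Treatment", "Infusion center - 2nd FL",
     _d(4, 1), _d(4, 7), None, None, _d(4, 7)),
    ("VID-7", "AID-12", "Treatment", "Infusion center - 2nd FL",
     _d(4, 1), _d(4, 8), None, None, _d(4, 8)),
]


def example_records() -> list[AppointmentRecord]:
    return [AppointmentRecord("PT-1", *row) for row in EXAMPLE_ROWS]


@pytest.fixture
def example_schedule() -> PatientSchedule:
    return PatientSchedule("PT-1", example_records(),
                           needs_flag=True, diagnosis_date=dt.date(2023, 1, 1))


@pytest.fixture
def example_csv_text() -> str:
    header = ("patient_id,vid,aid,reason,location,scheduled_on,scheduled_for,"
              "canceled_on,rescheduled_on,arrived_on\n")
    lines = [header]
    for row in EXAMPLE_ROWS:
        vid, aid, reason, loc = row[:4]
        dates = ["" if d is None else d.isoformat() for d in row[4:]]
        lines.append(",".join(["PT-1", vid, aid, reason, loc] + dates) + "\n")
    return "".join(lines)


AS_OF = dt.date(2023, 12, 31)

LOCATION_POOL = ["Site A - Ground", "Site A - 2nd FL", "Site B - Ground"]


def random_schedule(
    rng: np.random.Generator,
    max_aids: int = 30,
    patient_id: str = "R",
) -> PatientSchedule:
    """A random but valid schedule exercising every outcome and date shape.

    Dates are drawn in 2023 so everything is closed as of ``AS_OF``;
    arrived dates are drawn independently of scheduled dates to stress the
    out-of-order logic, and collisions between dates are common by design.
    """
    n = int(rng.integers(0, max_aids + 1))
    base = dt.date(2023, 1, 1)
    records = []
    for i in range(n):
        scheduled_on = base + dt.timedelta(days=int(rng.integers(0, 120)))
        scheduled_for = scheduled_on + dt.timedelta(days=int(rng.integers(0, 60)))
        kind = rng.choice(["arrived", "rescheduled", "canceled", "no_show"],
                          p=[0.6, 0.15, 0.15, 0.1])
        canceled_on = rescheduled_on = arrived_on = None
        if kind == "arrived":
            arrived_on = base + dt.timedelta(days=int(rng.integers(0, 180)))
        elif kind == "rescheduled":
            rescheduled_on = scheduled_on + dt.timedelta(
                days=int(rng.integers(0, 30)))
        elif kind == "canceled":
            canceled_on = scheduled_on + dt.timedelta(
                days=int(rng.integers(0, 30)))
        records.append(AppointmentRecord(
            patient_id=patient_id,
            vid=f"V{int(rng.integers(0, max(1, n // 2)))}",
            aid=f"A{i}",
            reason="visit",
            location=str(rng.choice(LOCATION_POOL)),
            scheduled_on=scheduled_on,
            scheduled_for=scheduled_for,
            canceled_on=canceled_on,
            rescheduled_on=rescheduled_on,
            arrived_on=arrived_on,
        ))
    return PatientSchedule(patient_id, records)
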