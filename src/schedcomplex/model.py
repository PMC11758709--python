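"""Domain model for patient appointment scheduling records.

An appointment event log is a set of rows, one per booked appointment
instance (AID).  Each AID belongs to a visit (VID) — a reason/location pair
that may span several AIDs, either because an appointment was rescheduled
(the replacement carries a new AID but the same VID) or because care is
delivered as a serial block of daily appointments.  Every AID carries five
dates at day granularity: when it was booked (``scheduled_on``), when care
was to happen (``scheduled_for``), and at most one terminal marker
(``canceled_on``, ``rescheduled_on``, ``arrived_on``).

The terminal fate of an AID is one of four exclusive outcomes — arrived,
rescheduled, canceled, or no-show — plus a PENDING state for appointments
still open at the observation date, which all downstream metrics exclude.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

log = logging.getLogger(__name__)

CSV_COLUMNS = [
    "patient_id",
    "vid",
    "aid",
    "reason",
    "location",
    "scheduled_on",
    "scheduled_for",
    "canceled_on",
    "rescheduled_on",
    "arrived_on",
]

SIDECAR_COLUMNS = ["patient_id", "diagnosis_date", "needs_flag"]


class ScheduleError(ValueError):
    """Raised for malformed schedule data (bad schema, duplicate AIDs, bad dates)."""


class Outcome(enum.Enum):
    """Terminal fate of an appointment.

    The four terminal outcomes are exclusive and total over closed
    appointments; PENDING marks appointments whose scheduled date has not
    yet passed and which carry no terminal marker.
    """

    ARRIVED = "arrived"
    RESCHEDULED = "rescheduled"
    CANCELED = "canceled"
    NO_SHOW = "no_show"
    PENDING = "pending"


#: Outcomes that count as "not arrived" in the metrics.
NONARRIVED_OUTCOMES = frozenset(
    {Outcome.RESCHEDULED, Outcome.CANCELED, Outcome.NO_SHOW}
)


@dataclass(frozen=True)
class AppointmentRecord:
    """One appointment instance (AID) with its booking and outcome dates."""

    patient_id: str
    vid: str
    aid: str
    reason: str
    location: str
    scheduled_on: dt.date
    scheduled_for: dt.date
    canceled_on: Optional[dt.date] = None
    rescheduled_on: Optional[dt.date] = None
    arrived_on: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.scheduled_on > self.scheduled_for:
            warnings.warn(
                f"AID {self.aid}: scheduled_on {self.scheduled_on} is after "
                f"scheduled_for {self.scheduled_for}; keeping the row as-is",
                stacklevel=2,
            )

    def dates(self) -> list[dt.date]:
        """All non-missing dates on the record."""
        out = [self.scheduled_on, self.scheduled_for]
        for d in (self.canceled_on, self.rescheduled_on, self.arrived_on):
            if d is not None:
                out.append(d)
        return out


@dataclass
class PatientSchedule:
    """All appointment records for one patient, plus optional annotations.

    ``needs_flag`` is an externally supplied binary label (transportation or
    housing insecurity indicated); ``diagnosis_date`` anchors the analysis
    window.
    """

    patient_id: str
    records: list[AppointmentRecord] = field(default_factory=list)
    needs_flag: Optional[bool] = None
    diagnosis_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.patient_id != self.patient_id:
                raise ScheduleError(
                    f"record AID {r.aid} has patient_id {r.patient_id!r}, "
                    f"expected {self.patient_id!r}"
                )
            if r.aid in seen:
                raise ScheduleError(
                    f"duplicate AID {r.aid!r} for patient {self.patient_id!r}"
                )
            seen.add(r.aid)

    def __len__(self) -> int:
        return len(self.records)

    def latest_date(self) -> Optional[dt.date]:
        """Most recent date appearing anywhere in the record set."""
        all_dates = [d for r in self.records for d in r.dates()]
        return max(all_dates) if all_dates else None


@dataclass(frozen=True)
class CsvDialect:
    """Input conventions for schedule CSV files.

    ``date_formats`` are tried in order for every non-empty date cell.  The
    default accepts ISO 8601 and US month/day/year; output is always ISO.
    """

    date_formats: tuple[str, ...] = ("%Y-%m-%d", "%m/%d/%Y")
    missing_tokens: frozenset[str] = frozenset({"", "—", "-", "NA", "N/A"})


DEFAULT_DIALECT = CsvDialect()


def _parse_date(
    cell: str, dialect: CsvDialect
) -> Optional[dt.date]:
    cell = cell.strip()
    if cell in dialect.missing_tokens:
        return None
    for fmt in dialect.date_formats:
        try:
            return dt.datetime.strptime(cell, fmt).date()
        except ValueError:
            continue
    raise ValueError(cell)


def read_schedule_csv(
    source: TextIO | str,
    dialect: CsvDialect = DEFAULT_DIALECT,
) -> list[PatientSchedule]:
    """Read an appointment event log into per-patient schedules.

    ``source`` is an open text stream or a path.  The file must have a
    header row with the canonical column names; date cells are ISO 8601 (or
    any format the dialect accepts) or empty for missing.  Returns one
    :class:`PatientSchedule` per distinct patient_id, in order of first
    appearance, with row order preserved within each patient.

    Raises :class:`ScheduleError` for a missing required column, a duplicate
    AID within a patient, or unparseable dates (all offending row numbers
    are listed).
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_schedule_csv(fh, dialect)

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        return []
    missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise ScheduleError(f"missing required column(s): {', '.join(missing)}")

    by_patient: dict[str, list[AppointmentRecord]] = {}
    bad_rows: list[tuple[int, str, str]] = []
    for i, row in enumerate(reader, start=2):  # 1-based, after header
        parsed: dict[str, Optional[dt.date]] = {}
        for col in ("scheduled_on", "scheduled_for", "canceled_on",
                    "rescheduled_on", "arrived_on"):
            try:
                parsed[col] = _parse_date(row[col] or "", dialect)
            except ValueError:
                bad_rows.append((i, col, row[col]))
                parsed[col] = None
        if bad_rows and bad_rows[-1][0] == i:
            continue
        if parsed["scheduled_on"] is None or parsed["scheduled_for"] is None:
            bad_rows.append((i, "scheduled_on/scheduled_for", "<empty>"))
            continue
        rec = AppointmentRecord(
            patient_id=row["patient_id"].strip(),
            vid=row["vid"].strip(),
            aid=row["aid"].strip(),
            reason=row["reason"],
            location=row["location"],
            scheduled_on=parsed["scheduled_on"],
            scheduled_for=parsed["scheduled_for"],
            canceled_on=parsed["canceled_on"],
            rescheduled_on=parsed["rescheduled_on"],
            arrived_on=parsed["arrived_on"],
        )
        by_patient.setdefault(rec.patient_id, []).append(rec)

    if bad_rows:
        detail = "; ".join(f"row {i}: {col}={val!r}" for i, col, val in bad_rows)
        raise ScheduleError(f"unparseable or missing dates: {detail}")

    return [PatientSchedule(pid, recs) for pid, recs in by_patient.items()]


def write_schedule_csv(
    schedules: Iterable[PatientSchedule], dest: TextIO | str
) -> None:
    """Write schedules back to the canonical CSV schema (ISO dates, UTF-8, LF)."""
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8", newline="\n") as fh:
            write_schedule_csv(schedules, fh)
            return

    writer = csv.writer(dest, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for sched in schedules:
        for r in sched.records:
            writer.writerow(
                [
                    r.patient_id,
                    r.vid,
                    r.aid,
                    r.reason,
                    r.location,
                    r.scheduled_on.isoformat(),
                    r.scheduled_for.isoformat(),
                    r.canceled_on.isoformat() if r.canceled_on else "",
                    r.rescheduled_on.isoformat() if r.rescheduled_on else "",
                    r.arrived_on.isoformat() if r.arrived_on else "",
                ]
            )


def read_sidecar_csv(
    source: TextIO | str, dialect: CsvDialect = DEFAULT_DIALECT
) -> dict[str, tuple[Optional[dt.date], Optional[bool]]]:
    """Read the per-patient sidecar: patient_id, diagnosis_date, needs_flag (0/1).

    Returns ``{patient_id: (diagnosis_date, needs_flag)}``; either value may
    be None when the cell is empty.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_sidecar_csv(fh, dialect)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        return {}
    missing = [c for c in SIDECAR_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise ScheduleError(
            f"sidecar missing required column(s): {', '.join(missing)}"
        )
    out: dict[str, tuple[Optional[dt.date], Optional[bool]]] = {}
    for i, row in enumerate(reader, start=2):
        try:
            diag = _parse_date(row["diagnosis_date"] or "", dialect)
        except ValueError:
            raise ScheduleError(
                f"sidecar row {i}: bad diagnosis_date {row['diagnosis_date']!r}"
            ) from None
        flag_cell = (row["needs_flag"] or "").strip()
        flag = None if flag_cell == "" else flag_cell in {"1", "true", "True"}
        out[row["patient_id"].strip()] = (diag, flag)
    return out


def annotate_schedules(
    schedules: Sequence[PatientSchedule],
    sidecar: dict[str, tuple[Optional[dt.date], Optional[bool]]],
) -> list[PatientSchedule]:
    """Attach sidecar diagnosis dates and needs flags to matching patients."""
    out = []
    for s in schedules:
        if s.patient_id in sidecar:
            diag, flag = sidecar[s.patient_id]
            s = PatientSchedule(s.patient_id, s.records, flag, diag)
        out.append(s)
    return out


def classify_outcome(record: AppointmentRecord, as_of: dt.date) -> Outcome:
    """Classify one appointment's terminal fate as of an observation date.

    Marker precedence is arrived > rescheduled > canceled; a marker-free
    appointment whose scheduled date has passed is a no-show, otherwise it
    is still PENDING.  Classification is total and exclusive.
    """
    if record.arrived_on is not None:
        return Outcome.ARRIVED
    if record.rescheduled_on is not None:
        return Outcome.RESCHEDULED
    if record.canceled_on is not None:
        return Outcome.CANCELED
    if record.scheduled_for < as_of:
        return Outcome.NO_SHOW
    return Outcome.PENDING


def action_date(record: AppointmentRecord) -> dt.date:
    """Date on which a non-arrived appointment's outcome event occurred.

    Cancel date for cancellations, reschedule (bump) date for reschedules,
    and the scheduled date itself for no-shows.  Calling this on an arrived
    record is a contract violation.
    """
    if record.arrived_on is not None:
        raise ValueError(
            f"action_date is undefined for arrived record AID {record.aid}"
        )
    if record.rescheduled_on is not None:
        return record.rescheduled_on
    if record.canceled_on is not None:
        return record.canceled_on
    return record.scheduled_for


def partition(
    schedule: PatientSchedule, as_of: dt.date
) -> tuple[list[AppointmentRecord], list[AppointmentRecord]]:
    """Split a schedule into (ARRIVED, NONARRIVED) record lists.

    NONARRIVED is the union of rescheduled, canceled, and no-show records;
    PENDING records are dropped.  Counts are conserved:
    ``len(arrived) + len(nonarrived) + n_pending == len(schedule)``.
    """
    arrived: list[AppointmentRecord] = []
    nonarrived: list[AppointmentRecord] = []
    for r in schedule.records:
        outcome = classify_outcome(r, as_of)
        if outcome is Outcome.ARRIVED:
            arrived.append(r)
        elif outcome in NONARRIVED_OUTCOMES:
            nonarrived.append(r)
    return arrived, nonarrived


def window_filter(
    schedule: PatientSchedule,
    start: Optional[dt.date],
    days: int = 365,
) -> PatientSchedule:
    """Restrict a schedule to appointments scheduled_for within a window.

    Keeps records with ``start <= scheduled_for < start + days`` (half-open).
    The window is keyed on scheduled_for — the date care was to occur.
    ``start`` is typically the diagnosis date; passing None is an error.
    """
    if start is None:
        raise ScheduleError(
            f"patient {schedule.patient_id!r}: window start date is required"
        )
    end = start + dt.timedelta(days=days)
    kept = [r for r in schedule.records if start <= r.scheduled_for < end]
    dropped = len(schedule.records) - len(kept)
    if dropped:
        log.info(
            "patient %s: %d record(s) outside window [%s, %s)",
            schedule.patient_id, dropped, start, end,
        )
    return PatientSchedule(
        schedule.patient_id, kept, schedule.needs_flag, schedule.diagnosis_date
    )
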