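"""Synthetic appointment-log generator for cohort-scale testing.

Real per-patient scheduling data cannot be shared, so this module emulates
its structure: a one-year window anchored at a diagnosis date; a care plan
mixing one-off appointments (consults, imaging, follow-ups) with serial
treatment blocks that share a visit identifier (VID) across consecutive
daily appointments; booking lead times with a heavy right tail (which is
what produces out-of-FIFO-order arrivals); per-appointment resolution into
arrived / rescheduled / canceled / no-show, where a reschedule spawns a
replacement appointment under the same VID booked on the bump date; a
fraction of cancellations whose cancel date deliberately lands on another
scheduling-action date (resolved cancellations); same-day appointment
pairs at different facilities; and a binary needs flag that scales the
disruption process for flagged patients.

All randomness flows from a single integer seed through per-patient
substreams, so a cohort is reproducible and independent of generation
order.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .model import AppointmentRecord, PatientSchedule

LOCATIONS = [
    "Hospital A - Ground",
    "Hospital A - 2nd FL",
    "Hospital B - Ground",
    "Hospital B - 3rd FL",
    "Imaging Center - 1st FL",
    "Infusion Center - 2nd FL",
]

REASONS = [
    "New consult",
    "Follow up",
    "Imaging",
    "Lab work",
    "Screening",
    "Echocardiogram",
    "Treatment",
]


@dataclass(frozen=True)
class TreatmentBlock:
    """Serial same-VID daily appointments (e.g. daily radiation/infusion).

    ``share`` is the fraction of a patient's planned appointments delivered
    as blocks of ``length`` consecutive days.
    """

    length: int = 5
    share: float = 0.3


@dataclass
class CohortParams:
    """Generator settings for one synthetic cohort.

    Defaults target the structure of a small urban oncology cohort: a
    median of roughly 88 appointment instances per patient over a one-year
    window, with rescheduled / canceled / no-show shares of roughly
    0.15 / 0.10 / 0.02 of closed appointments.  ``needs_multiplier`` scales
    the whole disruption process for flagged patients: the reschedule,
    cancel, and no-show odds, the rate at which cancellations are left
    unresolved, and the spread of booking lead times (erratic booking is
    what produces out-of-order arrivals).
    """

    n_patients: int = 38
    window_days: int = 365
    #: median of planned (pre-reschedule) appointments; lognormal count model
    appointments_median: float = 75.0
    appointments_sigma: float = 0.45
    min_appointments: int = 6
    #: booking lead time in days, lognormal
    lead_time_median_days: float = 12.0
    lead_time_sigma: float = 0.3
    p_reschedule: float = 0.18
    p_cancel: float = 0.085
    p_no_show: float = 0.02
    #: probability a cancellation's action date is placed on another action date
    p_resolved_cancel: float = 0.3
    #: probability a one-off care day is a same-day pair at two locations
    multi_location_day_rate: float = 0.85
    treatment_block: TreatmentBlock = field(default_factory=TreatmentBlock)
    reschedule_chain_depth: int = 1
    needs_fraction: float = 15 / 38
    needs_multiplier: float = 1.0
    seed: int = 0
    anchor_date: dt.date = dt.date(2023, 1, 1)

    def validate(self) -> None:
        for name in ("p_reschedule", "p_cancel", "p_no_show",
                     "p_resolved_cancel", "multi_location_day_rate",
                     "needs_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_reschedule + self.p_cancel + self.p_no_show > 1.0:
            raise ValueError(
                "p_reschedule + p_cancel + p_no_show exceeds 1"
            )
        if self.needs_multiplier < 0:
            raise ValueError("needs_multiplier must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.treatment_block.share <= 1.0:
            raise ValueError("treatment_block.share outside [0, 1]")
        if self.treatment_block.length < 1:
            raise ValueError("treatment_block.length must be >= 1")


@dataclass(frozen=True)
class PatientTruth:
    """Realized per-patient generation facts."""

    patient_id: str
    needs_flag: bool
    diagnosis_date: dt.date
    n_aids: int
    n_arrived: int
    n_rescheduled: int
    n_canceled: int
    n_no_show: int

    def as_row(self) -> dict:
        d = asdict(self)
        d["diagnosis_date"] = self.diagnosis_date.isoformat()
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Cohort-level ground truth emitted alongside the schedules."""

    seed: int
    patients: list[PatientTruth]

    def as_dict(self) -> dict:
        return {"seed": self.seed, "patients": [p.as_row() for p in self.patients]}


def _patient_rng(params: CohortParams, patient_index: int) -> np.random.Generator:
    # spawn-keyed substream: reproducible and independent of generation order
    ss = np.random.SeedSequence(params.seed, spawn_key=(patient_index,))
    return np.random.default_rng(ss)


def _scaled_probs(params: CohortParams, flagged: bool) -> tuple[float, float, float, float]:
    """(p_reschedule, p_cancel, p_no_show, p_unresolved) after the needs multiplier.

    Disruption probabilities are scaled on the odds scale and jointly capped
    so that arrivals stay the norm even under large multipliers; the
    unresolved-cancellation rate is scaled directly.
    """
    m = params.needs_multiplier if flagged else 1.0

    def odds_scale(p: float) -> float:
        if p >= 1.0:
            return 1.0
        o = m * p / (1.0 - p)
        return o / (1.0 + o)

    pr = odds_scale(params.p_reschedule)
    pc = odds_scale(params.p_cancel)
    pn = odds_scale(params.p_no_show)
    total = pr + pc + pn
    if total > 0.6:
        scale = 0.6 / total
        pr, pc, pn = pr * scale, pc * scale, pn * scale
    unresolved = min(1.0, (1.0 - params.p_resolved_cancel) * m)
    return pr, pc, pn, unresolved


def _lead_sigma(params: CohortParams, flagged: bool) -> float:
    # flagged patients book more erratically: heavier lead-time tail
    m = params.needs_multiplier if flagged else 1.0
    return min(1.2, params.lead_time_sigma * (1.0 + 0.5 * (m - 1.0)))


def _lead(rng: np.random.Generator, params: CohortParams,
          sigma: Optional[float] = None) -> int:
    days = rng.lognormal(math.log(params.lead_time_median_days),
                         params.lead_time_sigma if sigma is None else sigma)
    return max(1, int(round(days)))


@dataclass
class _Draft:
    vid: str
    reason: str
    location: str
    scheduled_on: dt.date
    scheduled_for: dt.date
    canceled_on: Optional[dt.date] = None
    rescheduled_on: Optional[dt.date] = None
    arrived_on: Optional[dt.date] = None
    wants_resolved_cancel: bool = False
    day_group: int = -1


def generate_patient(
    params: CohortParams,
    patient_index: int,
    needs_flag: Optional[bool] = None,
) -> tuple[PatientSchedule, PatientTruth]:
    """Generate one patient's schedule and its ground truth.

    The patient's substream is derived from ``params.seed`` and
    ``patient_index`` only, so the same pair always yields the same
    schedule.  ``needs_flag`` may be forced; by default it is drawn with
    probability ``params.needs_fraction``.
    """
    params.validate()
    rng = _patient_rng(params, patient_index)
    pid = f"P{patient_index:04d}"
    if needs_flag is None:
        needs_flag = bool(rng.random() < params.needs_fraction)
    diag = params.anchor_date + dt.timedelta(days=int(rng.integers(0, 365)))
    window_end = diag + dt.timedelta(days=params.window_days)
    horizon = params.window_days

    pr, pc, pn, p_unresolved = _scaled_probs(params, needs_flag)
    lead_sigma = _lead_sigma(params, needs_flag)

    n_planned = max(
        params.min_appointments,
        int(round(rng.lognormal(math.log(params.appointments_median),
                                params.appointments_sigma))),
    )
    block = params.treatment_block
    n_block_appts = int(round(block.share * n_planned))
    n_blocks = n_block_appts // block.length
    n_singles = n_planned - n_blocks * block.length

    drafts: list[_Draft] = []
    vid_counter = 0

    def next_vid() -> str:
        nonlocal vid_counter
        vid_counter += 1
        return f"{pid}-VID{vid_counter:04d}"

    # serial treatment blocks: one VID, booked together, consecutive days
    for _ in range(n_blocks):
        start_off = int(rng.integers(0, max(1, horizon - block.length)))
        book_off = max(0, start_off - _lead(rng, params, lead_sigma))
        vid = next_vid()
        loc = "Infusion Center - 2nd FL"
        for j in range(block.length):
            drafts.append(_Draft(
                vid=vid,
                reason="Treatment",
                location=loc,
                scheduled_on=diag + dt.timedelta(days=book_off),
                scheduled_for=diag + dt.timedelta(days=start_off + j),
            ))

    # one-off care days; some are same-day pairs at two locations
    i = 0
    group_counter = 0
    while i < n_singles:
        day_off = int(rng.integers(0, horizon))
        care_day = diag + dt.timedelta(days=day_off)
        pair = (
            i + 1 < n_singles
            and rng.random() < params.multi_location_day_rate
        )
        k = 2 if pair else 1
        locs = rng.choice(len(LOCATIONS), size=k, replace=False)
        group_counter += 1
        for j in range(k):
            book_off = max(0, day_off - _lead(rng, params, lead_sigma))
            drafts.append(_Draft(
                vid=next_vid(),
                reason=str(rng.choice(REASONS[:-1])),
                location=LOCATIONS[int(locs[j])],
                scheduled_on=diag + dt.timedelta(days=book_off),
                scheduled_for=care_day,
                day_group=group_counter,
            ))
        i += k

    # resolve every draft; reschedules spawn a replacement under the same
    # VID.  Same-day pairs share one trip, so the arrive/disrupt decision
    # is made once per care-day group; disrupted members then draw their
    # disruption type independently.
    p_total = pr + pc + pn
    final: list[_Draft] = []
    queue = [(d, params.reschedule_chain_depth) for d in drafts]
    group_disrupted: dict[int, bool] = {}
    while queue:
        d, depth = queue.pop(0)
        span = max(1, (d.scheduled_for - d.scheduled_on).days)
        if d.day_group in group_disrupted:
            disrupted = group_disrupted[d.day_group]
        else:
            disrupted = rng.random() < p_total
            if d.day_group >= 0:
                group_disrupted[d.day_group] = disrupted
        kind = ""
        if disrupted and p_total > 0:
            u = rng.random() * p_total
            kind = "reschedule" if u < pr else ("cancel" if u < pr + pc else "no_show")
            if kind == "reschedule" and depth == 0:
                # end of chain: cannot bump again; fall back to a cancellation
                kind = "cancel"
        if kind == "reschedule":
            bump_off = int(rng.integers(1, span + 1))
            d.rescheduled_on = d.scheduled_on + dt.timedelta(days=bump_off)
            bump = min(d.rescheduled_on, window_end - dt.timedelta(days=1))
            repl_for = bump + dt.timedelta(days=_lead(rng, params, lead_sigma))
            if repl_for >= window_end:
                repl_for = window_end - dt.timedelta(days=1)
            queue.append((_Draft(
                vid=d.vid,
                reason=d.reason,
                location=d.location,
                scheduled_on=bump,
                scheduled_for=repl_for,
            ), depth - 1))
        elif kind == "cancel":
            d.canceled_on = d.scheduled_on + dt.timedelta(
                days=int(rng.integers(1, span + 1))
            )
            d.wants_resolved_cancel = rng.random() >= p_unresolved
        elif kind == "no_show":
            pass  # no markers: a past scheduled_for classifies as no-show
        else:
            d.arrived_on = d.scheduled_for
        final.append(d)

    # second pass: place cancel dates on (resolved) or off (unresolved)
    # the patient's action dates — dense schedules would otherwise resolve
    # almost every cancellation by accident
    action_dates = sorted(
        {d.scheduled_on for d in final}
        | {d.arrived_on for d in final if d.arrived_on is not None}
    )
    action_set = set(action_dates)
    for d in final:
        if d.canceled_on is None:
            continue
        lo, hi = d.scheduled_on, d.scheduled_for
        if d.wants_resolved_cancel:
            candidates = [a for a in action_dates if lo <= a <= hi]
        else:
            span = (hi - lo).days
            candidates = [
                day
                for day in (lo + dt.timedelta(days=k) for k in range(1, span + 1))
                if day not in action_set
            ]
        if candidates:
            d.canceled_on = candidates[int(rng.integers(0, len(candidates)))]

    final.sort(key=lambda d: (d.scheduled_on, d.scheduled_for, d.vid))
    records = [
        AppointmentRecord(
            patient_id=pid,
            vid=d.vid,
            aid=f"{pid}-AID{k + 1:05d}",
            reason=d.reason,
            location=d.location,
            scheduled_on=d.scheduled_on,
            scheduled_for=d.scheduled_for,
            canceled_on=d.canceled_on,
            rescheduled_on=d.rescheduled_on,
            arrived_on=d.arrived_on,
        )
        for k, d in enumerate(final)
    ]
    schedule = PatientSchedule(pid, records, needs_flag, diag)
    truth = PatientTruth(
        patient_id=pid,
        needs_flag=needs_flag,
        diagnosis_date=diag,
        n_aids=len(records),
        n_arrived=sum(1 for d in final if d.arrived_on is not None),
        n_rescheduled=sum(1 for d in final if d.rescheduled_on is not None),
        n_canceled=sum(1 for d in final if d.canceled_on is not None),
        n_no_show=sum(
            1 for d in final
            if d.arrived_on is None and d.rescheduled_on is None
            and d.canceled_on is None
        ),
    )
    return schedule, truth


def generate_cohort(
    params: CohortParams,
) -> tuple[list[PatientSchedule], GroundTruth]:
    """Generate ``params.n_patients`` independent patients plus ground truth."""
    params.validate()
    schedules: list[PatientSchedule] = []
    truths: list[PatientTruth] = []
    for i in range(params.n_patients):
        s, t = generate_patient(params, i)
        schedules.append(s)
        truths.append(t)
    return schedules, GroundTruth(seed=params.seed, patients=truths)
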