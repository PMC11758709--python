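# schedcomplex

Per-patient **scheduling-complexity** metrics for appointment event logs.

Patients managing a serious illness can accumulate dozens of appointments a
year, and simple counts of no-shows or cancellations miss much of what makes
a schedule hard to live with: care booked and attended out of order,
disruptions that never get resolved, and days split across facilities.
`schedcomplex` computes a composite index of these three disruption sources
from ordinary scheduling-system exports, alongside the familiar count-based
ratios, so that care teams and health-services researchers can flag patients
whose scheduling patterns suggest they need navigation support.

## The metrics

Each appointment instance (AID) belongs to a visit (VID) and carries five
day-granular dates: *scheduled on* (booked), *scheduled for* (care date),
and at most one terminal marker (*canceled on*, *rescheduled on*, *arrived
on*). A marker-free appointment whose care date has passed is a no-show.
Over a one-year window per patient:

- **Sequence complexity** — count of arrived appointments that violate
  first-in-first-out order (some other appointment was booked strictly
  earlier yet attended strictly later), divided by the number of distinct
  arrived dates.
- **Resolution complexity** — fraction of non-arrived appointments whose
  action date (cancel date, bump date, or the scheduled date of a no-show)
  does not co-occur with any other scheduling action.
- **Location complexity** — proportion of arrived dates with appointments
  at two or more distinct locations.
- **Scheduling complexity** — the harmonic mean of the three,

  `SC = 3 / (1/seq + 1/res + 1/loc)`,

  defined as 0 when any component is 0.

The comparator is the **count-based adjustment**: the harmonic mean of the
rescheduled, canceled, and no-show ratios. Both composites are stratified
into low / medium / high by cohort quartiles and compared on a 3×3
contingency table with a Pearson chi-square test, and the share of
medium-or-high patients is reported by transportation/housing-needs group.

Two published phrasings of the algorithm differ in two details (which dates
resolve an action; the location denominator); both variants are available
via `ComplexityConfig`, with the prose-faithful variant as the default.

## Worked example

The canonical single-patient example — twelve appointments with one
cancellation, one reschedule chain, a same-day two-location imaging pair,
and a four-day treatment block:

```python
>>> from schedcomplex import scheduling_complexity, outcome_ratios
>>> profile = scheduling_complexity(patient)   # a PatientSchedule
>>> profile.sequence_complexity                # 2 out-of-order / 9 arrived dates
0.2222222222222222
>>> profile.resolution_complexity              # 1 dangling cancel / 2 non-arrived
0.5
>>> profile.location_complexity                # 1 two-location day / 9 arrived dates
0.1111111111111111
>>> profile.scheduling_complexity              # 3 / (9/2 + 2 + 9)
0.1935483870967742
>>> outcome_ratios(patient).rescheduled_ratio  # 1 reschedule / 12 appointments
0.08333333333333333
```

The two flagged out-of-order arrivals are the imaging pair: both were booked
after, but attended before, a long-lead echocardiogram.

The same pipeline from the shell, on a synthetic cohort:

```
schedcomplex simulate --seed 7 --n-patients 38 --out sim/
schedcomplex compute --schedule sim/schedule.csv --patients sim/patients.csv --out met/
schedcomplex compare --metrics met/metrics.csv --patients sim/patients.csv --out cmp/
```

`compute` logs the cohort quartiles of both composites and writes
`metrics.csv` (one row per patient: the three components, the composite,
the outcome ratios, and all intermediate counts). `compare` writes
`report.json`/`report.txt` with the stratum sizes, the 3×3 cross-tab, the
chi-square test, and — when needs flags are present — the medium-or-high
percentage per needs group. Every output directory contains the resolved
configuration, and a fixed seed makes the whole pipeline byte-reproducible.

Input is a plain CSV with columns `patient_id, vid, aid, reason, location,
scheduled_on, scheduled_for, canceled_on, rescheduled_on, arrived_on` (ISO
or M/D/YYYY dates, blank for missing), plus an optional per-patient sidecar
`patient_id, diagnosis_date, needs_flag`.

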