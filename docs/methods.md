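# Methods

## The scheduling-complexity model

The unit of analysis is the appointment instance (AID). A visit (VID) — a
reason/location pair — may span several AIDs, because rescheduling retires
one AID and books a replacement under the same VID, and because serial
treatments (e.g. daily infusions) are booked as a block of same-VID AIDs.
All dates are at day granularity; there is no time-of-day model.

Classification of an AID's terminal fate is total and exclusive, with
marker precedence **arrived > rescheduled > canceled > no-show**: a row
carrying several markers is classified by the strongest one, on the logic
that an arrival recorded on a row also carrying a cancel/bump marker means
the chain completed under that AID. A marker-free AID whose scheduled date
has passed the observation date (`as_of`) is a no-show; one whose scheduled
date has not passed is *pending* and is excluded from every metric, keeping
all denominators well defined over a closed window.

Per patient, over a window of (by default) 365 days keyed on
`scheduled_for` and anchored at the diagnosis date:

- **Sequence complexity** = (# arrived AIDs x for which some arrived AID y
  was booked strictly earlier and attended strictly later) / (# distinct
  arrived dates). Strict inequalities mean same-day ties never create
  out-of-order flags: at day granularity the direction of a tie is
  unknowable. The numerator counts AIDs while the denominator counts
  dates; this mismatch is retained deliberately, so the value can exceed 1
  when several same-date AIDs are each out of order. No clamping is done.
- **Resolution complexity** = (# non-arrived AIDs whose action date is in
  no check set) / (# non-arrived AIDs). The action date is the cancel
  date, the bump date, or the scheduled date for a no-show.
- **Location complexity** = (# arrived dates spanning ≥ 2 distinct
  locations) / denominator. Locations compare as exact strings after
  whitespace normalisation, case-sensitive: two floors of one building are
  distinct locations.
- **Scheduling complexity** = harmonic mean of the three components, with
  the convention that the composite is 0 whenever any component is 0 (the
  harmonic mean is undefined at 0, and "no disruption of one kind → low
  complexity" should be monotone). Components are equally weighted.

Note the harmonic mean is *not* below the smallest component; it lies
between `min` and `3·min` of its inputs. The composite is therefore
dominated by — but can exceed — its weakest component, which is exactly
the property wanted: one absent disruption source pulls the index down
hard, and the property tests assert the `[min, 3·min]` envelope.

### Config variants

Two published phrasings of the algorithm disagree on two details, so both
are implemented behind `ComplexityConfig`:

| switch | default (prose-faithful) | literal-pseudocode variant |
|---|---|---|
| resolution check set | arrived dates ∪ booking dates of the patient's other AIDs | arrived dates only |
| location denominator | all distinct arrived dates | arrived dates with ≥ 2 AIDs |

The default check set treats a bump whose replacement was booked on the
bump date as resolved — which the worked example's reschedule chain clearly
intends — while the literal variant reproduces the pseudocode check against
arrived dates only. On the worked example the defaults give resolution 1/2
and location 1/9; the literal variant gives 1.0 for both. The resolution
denominator is all non-arrived AIDs (reschedules included) in both
variants. Which variant produced the original cohort results is not
determinable from the published record; the prose-faithful variant is the
default here.

The comparator **count-based adjustment** is the harmonic mean of the
rescheduled, canceled, and no-show ratios with the same zero convention
(chosen for comparability; note a quarter of a typical cohort has a zero
no-show ratio, so the convention binds often). Ratios are over unique
non-pending AIDs.

## Stratification and comparison

Quartiles use linear interpolation of order statistics (numpy's default).
A value ≤ Q1 is LOW, ≥ Q3 is HIGH, else MEDIUM — boundary patients fall
toward the tails, conservative toward identifying need. Degenerate inputs
(< 4 values, or Q1 = Q3) yield all-MEDIUM with a warning. For n distinct
values the LOW and HIGH bins land within one patient of n/4 each (a
38-patient cohort splits 10/18/10).

The two stratifications are crossed in a 3×3 table and tested with a plain
Pearson chi-square (scipy, no continuity correction, df = 4), matching the
published analysis even though expected counts are small; no exact test is
substituted. A zero row/column margin is an error rather than a silent
drop. The needs association reports, per needs-flag group, the count and
percentage (1 decimal) of patients stratified MEDIUM or HIGH.

## Synthetic cohort generator

No per-patient scheduling data is publicly available, so the generator
emulates the *structure* the metrics assume, with defaults set to the
published cohort descriptives: 38 patients, a one-year window, a lognormal
planned-appointment count (median 75, σ = 0.45, yielding a median of ~88
total AIDs once reschedule replacements are added, IQR ≈ 50–60), and
per-appointment disruption probabilities p_reschedule = 0.18,
p_cancel = 0.085, p_no_show = 0.02, which realize rescheduled / canceled /
no-show ratios near 0.15 / 0.11 / 0.02.

Structural features, each exercising one metric:

- **Lead times** (booking to care date) are lognormal, median 12 days,
  σ = 0.3. Lead-time dispersion is the sole source of out-of-order
  arrivals; σ = 0.3 realizes a median sequence complexity ≈ 0.26.
- **Treatment blocks**: 30% of planned appointments are delivered as
  5-day same-VID blocks booked together — the serial-treatment pattern.
- **Reschedules** spawn exactly one replacement AID under the same VID,
  booked on the bump date (single-hop chains by default; depth is
  configurable). An end-of-chain reschedule draw falls back to a
  cancellation.
- **Cancellation resolution**: with probability p_resolved_cancel = 0.3
  the cancel date is placed on another of the patient's action dates;
  otherwise it is placed off all of them. The explicit off-placement
  matters: schedules this dense would otherwise resolve almost every
  cancellation by accident, collapsing resolution complexity.
- **Multi-location days**: 85% of one-off care days are booked as same-day
  pairs at two distinct locations from a six-entry "Facility - Floor"
  catalog. Same-day appointments share one trip, so the arrive/disrupt
  decision is made once per care day (members of a disrupted day then draw
  their disruption types independently). Without this correlation,
  independent member failures would make multi-location days die off
  quadratically in the disruption rate and reverse the needs-flag effect.
- **Needs flag**: drawn at rate 15/38 (or forced per patient). A
  multiplier m scales the flagged patients' disruption process: the three
  outcome probabilities on the odds scale (jointly capped so total
  disruption ≤ 0.6 — arrivals stay the norm), the unresolved-cancellation
  rate (×m, capped at 1), and the lead-time σ (×(1 + (m−1)/2), capped at
  1.2). Scaling only the raw outcome probabilities would leave the
  unresolved *fraction* unchanged and starve the location channel, so the
  multiplier would barely move the composite; the broader definition makes
  "flagged patients have more disrupted schedules" hold as a distributional
  property, verified by rank tests in the suite (m = 3 separates groups at
  p < 0.01 with 500 per group; m = 1 is null).

Randomness flows from one integer seed through spawn-keyed per-patient
substreams (`SeedSequence(seed, spawn_key=(patient_index,))`), so cohorts
are reproducible and independent of generation order.

At the default conditions the generated cohort's component medians are
sequence ≈ 0.26, resolution ≈ 0.33, location ≈ 0.43, composite ≈ 0.31 —
close to, though not exactly matching, the published cohort medians (0.20,
0.37, 0.46, 0.24); the generator is a structural emulation, not a fit.
What it does not model: clinic capacity and provider availability, seasonal
or weekday structure, multi-hop reschedule chains (by default), reasons'
correlation with locations, and any real patient behaviour beyond the
configured rates — so passing tests demonstrate algorithmic correctness
and direction-level behaviour, not clinical validity on real data.

## Numerical and engineering choices

- Metrics are exact rational arithmetic in floating point (counts divided
  once); no tolerance is needed beyond float equality, and profiles are
  bit-identical across runs and record orderings.
- The out-of-order scan is the O(n²) pairwise definition, vectorised with
  numpy broadcasting; at n ≤ a few hundred AIDs per patient-year this is
  microseconds, and the tests compare it against an independent pure-loop
  implementation.
- Chi-square p-values come from scipy's upper-tail chi-square survival
  function.
- CSV I/O accepts ISO 8601 and M/D/YYYY dates (configurable dialect),
  writes ISO only, UTF-8 with LF. `scheduled_on > scheduled_for` warns but
  loads — real exports are messy; duplicate AIDs within a patient and
  unparseable dates are hard errors with row numbers.
- The window is half-open `[start, start + days)` and keyed on
  `scheduled_for` (when care occurs); keying on booking or action dates is
  defensible but not what the window is for.
- Same-day cancellation is not treated as a no-show; the classification
  follows markers only.

## Known limitations

- Sequence complexity above 1 is possible by construction (AID numerator,
  date denominator); downstream quartile binning is rank-based and
  unaffected, but the value is not a proportion.
- With ≤ ~8 patients, quartile strata are coarse and the chi-square test
  on a 3×3 table is unreliable (expected counts ≪ 5); the CLI warns below
  4 patients but computes anyway, mirroring the published analysis' use of
  the plain test at n = 38.
- The equal-weight harmonic mean is a deliberate naïve aggregation;
  component weighting is future work, not implemented.
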