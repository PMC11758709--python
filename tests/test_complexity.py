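"""Complexity components, the composite, and their independent oracles."""

import dataclasses
import datetime as dt
import math

import numpy as np
import pytest

from schedcomplex import (
    ComplexityConfig,
    DEFAULT_CONFIG,
    LITERAL_CONFIG,
    PatientSchedule,
    harmonic_mean,
    location_complexity,
    partition,
    resolution_complexity,
    scheduling_complexity,
    sequence_complexity,
)
from schedcomplex.complexity import resolution_check_dates

from conftest import AS_OF, random_schedule
from oracles import (
    oracle_harmonic,
    oracle_location,
    oracle_resolution,
    oracle_sequence,
)


class TestWorkedExample:
    """The 12-appointment example patient, under both config variants."""

    def test_sequence(self, example_schedule):
        arrived, _ = partition(example_schedule, AS_OF)
        frac, count, n_dates = sequence_complexity(arrived)
        assert (count, n_dates) == (2, 9)
        assert frac == pytest.approx(2 / 9)
        # the two flagged arrivals straddle the long-lead echocardiogram
        flagged = {
            r.aid for r in arrived
            if any(y.scheduled_on < r.scheduled_on and y.arrived_on > r.arrived_on
                   for y in arrived)
        }
        assert flagged == {"AID-5", "AID-6"}

    def test_resolution_default_config(self, example_schedule):
        arrived, nonarrived = partition(example_schedule, AS_OF)
        check = resolution_check_dates(example_schedule, arrived, DEFAULT_CONFIG)
        frac, unresolved = resolution_complexity(nonarrived, check)
        # the bump lands on the replacement's booking date: resolved;
        # the lone cancellation matches nothing: unresolved
        assert (frac, unresolved) == (0.5, 1)

    def test_resolution_literal_config(self, example_schedule):
        arrived, nonarrived = partition(example_schedule, AS_OF)
        check = resolution_check_dates(example_schedule, arrived, LITERAL_CONFIG)
        frac, unresolved = resolution_complexity(nonarrived, check)
        assert (frac, unresolved) == (1.0, 2)

    def test_location_default_config(self, example_schedule):
        arrived, _ = partition(example_schedule, AS_OF)
        frac, count = location_complexity(arrived, DEFAULT_CONFIG)
        assert count == 1  # the two-floor imaging day
        assert frac == pytest.approx(1 / 9)

    def test_location_literal_config(self, example_schedule):
        arrived, _ = partition(example_schedule, AS_OF)
        frac, count = location_complexity(arrived, LITERAL_CONFIG)
        assert (frac, count) == (1.0, 1)

    def test_full_profile_default(self, example_schedule):
        p = scheduling_complexity(example_schedule, DEFAULT_CONFIG, AS_OF)
        assert p.sequence_complexity == pytest.approx(2 / 9)
        assert p.resolution_complexity == pytest.approx(1 / 2)
        assert p.location_complexity == pytest.approx(1 / 9)
        assert p.scheduling_complexity == pytest.approx(
            3 / (9 / 2 + 2 + 9))  # ~0.1935
        assert p.nonarrived_count == 2
        assert p.unique_arrived_date_count == 9


class TestDegenerateSchedules:
    def test_empty_schedule_all_zero(self):
        p = scheduling_complexity(PatientSchedule("P"), as_of=AS_OF)
        assert (p.sequence_complexity, p.resolution_complexity,
                p.location_complexity, p.scheduling_complexity) == (0, 0, 0, 0)

    def test_single_arrival_all_zero(self, example_schedule):
        s = PatientSchedule("P", [
            dataclasses.replace(example_schedule.records[0], patient_id="P")])
        p = scheduling_complexity(s, as_of=AS_OF)
        assert p.scheduling_complexity == 0.0

    def test_fifo_schedule_has_zero_sequence(self, example_schedule):
        # booked order equals arrival order -> no inversions
        arrived, _ = partition(example_schedule, AS_OF)
        fifo = sorted(arrived, key=lambda r: r.scheduled_on)
        shifted = [
            dataclasses.replace(
                r, arrived_on=dt.date(2023, 1, 1) + dt.timedelta(days=3 * i))
            for i, r in enumerate(fifo)
        ]
        frac, count, _ = sequence_complexity(shifted)
        assert (frac, count) == (0.0, 0)

    def test_same_day_booking_ties_not_flagged(self):
        # two appointments booked the same day, arrived in reverse order:
        # strict inequality means ties are never out-of-order
        recs = [_mk(0, dt.date(2023, 2, 1)), _mk(1, dt.date(2023, 1, 20))]
        frac, count, _ = sequence_complexity(recs)
        assert (frac, count) == (0.0, 0)


def _mk(i, arrived_on):
    from schedcomplex import AppointmentRecord

    return AppointmentRecord(
        patient_id="P", vid="V", aid=f"A{i}", reason="r", location="L",
        scheduled_on=dt.date(2023, 1, 10),
        scheduled_for=arrived_on, arrived_on=arrived_on)


class TestHarmonicMean:
    def test_equal_components_identity(self):
        for x in (0.01, 0.2, 1.0, 3.7):
            assert harmonic_mean([x, x, x]) == pytest.approx(x)

    def test_cohort_median_components(self):
        # harmonic mean of the three component medians; illustrative value
        assert harmonic_mean([0.2, 0.372, 0.464]) == pytest.approx(
            0.30477, abs=1e-4)

    def test_zero_convention(self):
        assert harmonic_mean([0.0, 0.5, 0.9]) == 0.0

    def test_empty_is_contract_violation(self):
        with pytest.raises(ValueError):
            harmonic_mean([])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean([-0.1, 0.5, 0.5])

    def test_bound_and_identity_properties(self):
        # the harmonic mean sits between min and 3*min: the smallest
        # component dominates the composite
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            trip = rng.uniform(0, 1.5, size=3)
            if rng.random() < 0.2:
                trip[rng.integers(0, 3)] = 0.0
            h = harmonic_mean(list(trip))
            if (trip > 0).all():
                assert trip.min() - 1e-12 <= h <= 3 * trip.min() + 1e-12
                assert h == pytest.approx(oracle_harmonic(list(trip)))
            else:
                assert h == 0.0


class TestOracleEquivalence:
    """Components match independent brute-force implementations exactly."""

    @pytest.mark.parametrize("config", [DEFAULT_CONFIG, LITERAL_CONFIG],
                             ids=["prose", "pseudocode"])
    def test_random_schedules(self, config):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            s = random_schedule(rng)
            arrived, nonarrived = partition(s, AS_OF)
            profile = scheduling_complexity(s, config, AS_OF)

            ooo, n_dates = oracle_sequence(arrived)
            assert profile.out_of_order_count == ooo
            assert profile.unique_arrived_date_count == n_dates

            check = resolution_check_dates(s, arrived, config)
            assert profile.unresolved_count == oracle_resolution(
                nonarrived, check)

            numer, denom = oracle_location(
                arrived,
                config.location_denominator.value == "all_arrived_dates")
            assert profile.multi_location_date_count == numer
            if denom:
                assert profile.location_complexity == pytest.approx(
                    numer / denom)
            else:
                assert profile.location_complexity == 0.0


class TestInvariants:
    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            s = random_schedule(rng)
            perm = list(np.random.default_rng(1).permutation(len(s.records)))
            shuffled = PatientSchedule(
                s.patient_id, [s.records[i] for i in perm])
            assert scheduling_complexity(s, as_of=AS_OF) == \
                scheduling_complexity(shuffled, as_of=AS_OF)

    def test_extra_unresolved_cancel_never_decreases_resolution(self):
        from schedcomplex import AppointmentRecord

        rng = np.random.default_rng(9)
        for k in range(30):
            s = random_schedule(rng)
            before = scheduling_complexity(s, as_of=AS_OF)
            extra = AppointmentRecord(
                patient_id=s.patient_id, vid="VX", aid="EXTRA",
                reason="r", location="L",
                scheduled_on=dt.date(2022, 6, 1),
                scheduled_for=dt.date(2022, 7, 1),
                canceled_on=dt.date(2022, 6, 15))  # far from all 2023 dates
            bigger = PatientSchedule(s.patient_id, [*s.records, extra])
            after = scheduling_complexity(bigger, as_of=AS_OF)
            assert after.resolution_complexity >= before.resolution_complexity

    def test_composite_dominated_by_smallest_component(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            p = scheduling_complexity(random_schedule(rng), as_of=AS_OF)
            comps = (p.sequence_complexity, p.resolution_complexity,
                     p.location_complexity)
            if all(c > 0 for c in comps):
                assert min(comps) - 1e-12 <= p.scheduling_complexity \
                    <= 3 * min(comps) + 1e-12
            else:
                assert p.scheduling_complexity == 0.0

    def test_bit_identical_determinism(self):
        rng1, rng2 = np.random.default_rng(77), np.random.default_rng(77)
        s1, s2 = random_schedule(rng1), random_schedule(rng2)
        assert scheduling_complexity(s1, as_of=AS_OF) == \
            scheduling_complexity(s2, as_of=AS_OF)
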