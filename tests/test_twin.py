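"""Digital twin: arrival process, failures/repairs, assignment semantics
and bookkeeping invariants."""

import numpy as np
import pytest

from mrisched.calibration import RateProfile, default_diurnal_profile
from mrisched.twin import (
    BUSY,
    FAILED,
    IDLE,
    FailureModel,
    IllegalActionError,
    sample_arrival_times,
    sample_repair_duration,
    simulate_operating_failures,
)


class TestArrivalSampling:
    def test_zero_profile_yields_no_arrivals(self, rng):
        profile = RateProfile((0.0,) * 24)
        assert len(sample_arrival_times(profile, 10_000, rng)) == 0

    def test_peak_only_profile_restricts_support(self, rng):
        profile = default_diurnal_profile(4.0, 0.0)
        times = sample_arrival_times(profile, 5 * 1440, rng)
        assert len(times) > 0
        minute_of_day = times % 1440
        assert np.all((minute_of_day >= 8 * 60) & (minute_of_day < 17 * 60))

    def test_times_are_sorted_and_in_range(self, rng):
        profile = default_diurnal_profile(4.0, 0.5)
        times = sample_arrival_times(profile, 1440, rng)
        assert np.all(np.diff(times) > 0)
        assert times.min() >= 0 and times.max() < 1440

    def test_homogeneous_mean_count_matches_poisson(self):
        # rate 2/h over one day: counts ~ Poisson(48)
        profile = RateProfile((2.0,) * 24)
        n_seeds = 1000
        counts = [
            len(sample_arrival_times(profile, 1440, np.random.default_rng(s)))
            for s in range(n_seeds)
        ]
        se = np.sqrt(48.0 / n_seeds)
        assert abs(np.mean(counts) - 48.0) < 3 * se

    def test_seeded_determinism(self):
        profile = default_diurnal_profile(4.0, 0.5)
        a = sample_arrival_times(profile, 1440, 77)
        b = sample_arrival_times(profile, 1440, 77)
        np.testing.assert_array_equal(a, b)


class TestFailureModel:
    def test_hazard_compounds_to_hourly_probability(self):
        model = FailureModel(p_fail_per_hour=0.01, mean_repair_hours=3.0)
        assert (1 - model.per_minute_hazard) ** 60 == pytest.approx(0.99)
        assert FailureModel(0.0, 1.0).per_minute_hazard == 0.0
        assert FailureModel(1.0, 1.0).per_minute_hazard == 1.0

    def test_repair_sampler_mean_and_determinism(self):
        model = FailureModel(0.01, 3.0)
        draws = sample_repair_duration(model, np.random.default_rng(1), size=100_000)
        assert draws.min() > 0
        assert draws.mean() == pytest.approx(180.0, rel=0.02)
        one = sample_repair_duration(model, np.random.default_rng(5))
        two = sample_repair_duration(model, np.random.default_rng(5))
        assert one == two

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            FailureModel(p_fail_per_hour=1.5)
        with pytest.raises(ValueError):
            FailureModel(mean_repair_hours=0.0)

    def test_vectorized_operating_failures_matches_stepped_path(self, make_twin):
        """The vectorized per-operating-minute hazard draw agrees with the
        failure frequency produced by advance_one_minute."""
        p_fail = 0.2  # high hazard so a short run has narrow relative error
        hours = 600
        minutes = hours * 60
        # stepped path: one machine, backlog large enough to stay busy
        n_jobs = minutes // 30 + 50
        twin = make_twin(
            arrivals=[0.0] * n_jobs,
            durations=[30.0] * n_jobs,
            n_machines=1,
            p_fail=p_fail,
            mean_repair_hours=0.05,  # short repairs keep operating share high
            seed=11,
        )
        failures = 0
        while twin.clock < minutes:
            m = twin.machines[0]
            if m.status == IDLE and twin.queue:
                twin.assign(twin.queue[0].id, 0)
            twin.advance_one_minute()
        failures = sum(1 for e in twin.event_log if e["type"] == "failure")
        operating_hours = twin.machines[0].cumulative_busy / 60.0
        stepped_rate = failures / operating_hours
        model = FailureModel(p_fail, 1.0)
        vec_failures = simulate_operating_failures(
            model, operating_hours, np.random.default_rng(3)
        )
        vec_rate = vec_failures / operating_hours
        expected = 60 * model.per_minute_hazard  # failures per operating hour
        se = np.sqrt(expected / operating_hours)
        assert abs(stepped_rate - expected) < 3 * se
        assert abs(vec_rate - expected) < 3 * se


class TestTransitions:
    def test_zero_hazard_means_no_downtime(self, make_twin):
        twin = make_twin([0.0, 0.0], [35.0, 20.0], n_machines=2, p_fail=0.0)
        twin.assign(0, 0)
        twin.assign(1, 1)
        for _ in range(200):
            twin.advance_one_minute()
        assert twin.total_down_minutes() == 0.0
        assert all(m.status != FAILED for m in twin.machines)
        assert len(twin.completed) == 2

    def test_certain_hazard_fails_in_first_operating_minute(self, make_twin):
        twin = make_twin([0.0], [30.0], n_machines=1, p_fail=1.0)
        twin.assign(0, 0)
        twin.advance_one_minute()
        machine = twin.machines[0]
        assert machine.status == FAILED
        assert machine.repair_until is not None
        patient = twin.queue[0]  # interrupted patient back at the head
        assert patient.id == 0
        assert patient.arrival_time == 0.0  # original arrival retained
        assert patient.start_time is None

    def test_assign_postconditions_and_zero_wait(self, make_twin):
        twin = make_twin([0.0, 0.0], [10.0, 10.0])
        for _ in range(10):
            twin.advance_one_minute()
        q_before = len(twin.queue)
        twin.assign(0, 1)
        assert len(twin.queue) == q_before - 1
        assert twin.machines[1].status == BUSY
        assert twin.machines[1].current_patient == 0
        assert twin.patients[0].wait == pytest.approx(10.0)
        # a patient assigned the minute it arrives waits zero
        twin2 = make_twin([0.0], [10.0])
        twin2.assign(0, 0)
        assert twin2.patients[0].wait == 0.0

    def test_illegal_assignments_raise(self, make_twin):
        twin = make_twin([0.0, 0.0], [30.0, 30.0], n_machines=2, p_fail=1.0)
        twin.assign(0, 0)
        with pytest.raises(IllegalActionError):
            twin.assign(1, 0)  # machine busy
        with pytest.raises(IllegalActionError):
            twin.assign(0, 1)  # patient already in service
        twin.advance_one_minute()  # certain failure: machine 0 now failed
        with pytest.raises(IllegalActionError):
            twin.assign(0, 0)  # machine failed
        with pytest.raises(IllegalActionError):
            twin.assign(99, 1)  # no such patient

    def test_busy_minutes_equal_served_minutes(self, make_twin):
        twin = make_twin(
            [0.0, 0.0, 0.0], [10.0, 20.0, 30.0], n_machines=1, p_fail=0.0
        )
        for _ in range(100):
            if twin.machines[0].status == IDLE and twin.queue:
                twin.assign(twin.queue[0].id, 0)
            twin.advance_one_minute()
        assert len(twin.completed) == 3
        assert twin.machines[0].cumulative_busy == pytest.approx(60.0)
        waits = sorted(p.wait for p in twin.patients)
        assert waits == pytest.approx([0.0, 10.0, 30.0])

    def test_completion_time_is_start_plus_service(self, make_twin):
        twin = make_twin([0.0], [12.4], n_machines=1)
        twin.assign(0, 0)
        for _ in range(14):
            twin.advance_one_minute()
        patient = twin.completed[0]
        assert patient.completion_time == patient.start_time + 13.0  # ceil to minutes
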