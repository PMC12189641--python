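"""Minute-resolution discrete-event model of an MRI suite.

The state tracks the waiting queue, per-machine status (idle / busy /
failed), every admitted patient and an append-only event log.  Time moves
in one-minute ticks; within a tick events resolve in a fixed order —
repairs complete, exams complete, failures are drawn, new arrivals are
admitted — and the scheduling decision is taken between ticks.  The fixed
ordering frees capacity before each decision and makes runs bit-for-bit
reproducible.

Machine failures are Bernoulli per *operating* minute with hazard
``1 - (1 - p_fail_per_hour)**(1/60)`` (so the per-operating-hour failure
probability is exactly ``p_fail_per_hour``); idle and failed machines carry
no failure risk.  Repairs last an exponential time.  A failure mid-exam
sends the patient back to the head of the queue with the original arrival
time; the exam restarts from zero when reassigned.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import RateProfile

__all__ = [
    "IDLE",
    "BUSY",
    "FAILED",
    "IllegalActionError",
    "FailureModel",
    "Patient",
    "MachineState",
    "DigitalTwin",
    "sample_repair_duration",
    "simulate_operating_failures",
    "sample_arrival_times",
    "write_event_log",
    "write_patient_table",
]

IDLE = "idle"
BUSY = "busy"
FAILED = "failed"


class IllegalActionError(RuntimeError):
    """An assignment violated its preconditions (machine not idle, patient
    not in the queue, or an out-of-range index)."""


@dataclass(frozen=True)
class FailureModel:
    """Bernoulli-per-operating-minute breakdowns with exponential repairs."""

    p_fail_per_hour: float = 0.01
    mean_repair_hours: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fail_per_hour <= 1.0):
            raise ValueError("p_fail_per_hour must lie in [0, 1]")
        if not (np.isfinite(self.mean_repair_hours) and self.mean_repair_hours > 0):
            raise ValueError("mean_repair_hours must be > 0")

    @property
    def per_minute_hazard(self) -> float:
        """Compounded per-operating-minute hazard; exact per-hour probability."""
        if self.p_fail_per_hour >= 1.0:
            return 1.0
        return 1.0 - (1.0 - self.p_fail_per_hour) ** (1.0 / 60.0)

    @property
    def mean_repair_minutes(self) -> float:
        return self.mean_repair_hours * 60.0


def sample_repair_duration(
    failure: FailureModel,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Exponential repair duration(s) in minutes with the model's mean."""
    draw = rng.exponential(failure.mean_repair_minutes, size=size)
    return float(draw) if size is None else draw


def simulate_operating_failures(
    failure: FailureModel,
    operating_hours: float,
    rng: np.random.Generator,
    chunk: int = 1_000_000,
) -> int:
    """Failures of a machine held continuously busy for ``operating_hours``.

    Draws the same Bernoulli(per-minute hazard) that
    :meth:`DigitalTwin.advance_one_minute` applies to a busy machine, but
    vectorized, so long calibration checks stay cheap.
    """
    minutes = int(round(operating_hours * 60.0))
    if minutes < 0:
        raise ValueError("operating_hours must be non-negative")
    p = failure.per_minute_hazard
    count = 0
    remaining = minutes
    while remaining > 0:
        m = min(chunk, remaining)
        count += int((rng.random(m) < p).sum())
        remaining -= m
    return count


def sample_arrival_times(
    profile: RateProfile,
    horizon: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Non-homogeneous Poisson arrival times on [0, horizon) minutes.

    Thinning: candidate events arrive at the envelope rate
    ``profile.max_rate`` and are kept with probability λ(t)/max_rate.
    Deterministic given the generator state; an all-zero profile yields an
    empty sequence.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lam_max = profile.max_rate
    if lam_max <= 0:
        return np.empty(0, dtype=float)
    per_minute = lam_max / 60.0
    times: list[float] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / per_minute)
        if t >= horizon:
            break
        if rng.random() * lam_max <= profile.rate_at(t):
            times.append(t)
    return np.asarray(times, dtype=float)


@dataclass
class Patient:
    id: int
    arrival_time: float
    priority: int
    #: Nominal exam duration in minutes, sampled at arrival and hidden from
    #: agent observations.  Kept fixed if the patient is re-served after an
    #: interruption.
    exam_duration: float
    start_time: Optional[float] = None
    completion_time: Optional[float] = None

    @property
    def wait(self) -> Optional[float]:
        """Minutes from arrival to exam start, once started."""
        if self.start_time is None:
            return None
        return self.start_time - self.arrival_time


@dataclass
class MachineState:
    id: int
    status: str = IDLE
    busy_until: Optional[float] = None
    repair_until: Optional[float] = None
    current_patient: Optional[int] = None
    cumulative_busy: float = 0.0
    cumulative_down: float = 0.0


class DigitalTwin:
    """The simulator proper.  Construct with pre-sampled, index-aligned
    arrival times, exam durations and priorities (one entry per eventual
    patient) plus independent failure/repair random streams, then drive it
    with :meth:`assign` and :meth:`advance_one_minute`.

    ``round_durations=True`` (production mode) rounds exam occupancy up to
    whole minutes; validation mode (``False``) keeps fractional busy-until
    times so exponential-service queueing checks are not distorted.
    """

    def __init__(
        self,
        n_machines: int,
        arrival_times: Sequence[float],
        durations: Sequence[float],
        priorities: Sequence[int],
        failure: FailureModel | None = None,
        rng_failures: np.random.Generator | None = None,
        rng_repairs: np.random.Generator | None = None,
        round_durations: bool = True,
    ) -> None:
        if n_machines < 1:
            raise ValueError("need at least one machine")
        arr = np.asarray(arrival_times, dtype=float)
        dur = np.asarray(durations, dtype=float)
        pri = np.asarray(priorities, dtype=int)
        if not (len(arr) == len(dur) == len(pri)):
            raise ValueError("arrival, duration and priority arrays must align")
        if len(arr) and np.any(np.diff(arr) < 0):
            raise ValueError("arrival times must be non-decreasing")
        if np.any(dur <= 0):
            raise ValueError("exam durations must be positive")
        if len(pri) and not np.all((pri >= 1) & (pri <= 3)):
            raise ValueError("priorities must be 1, 2 or 3")

        self.failure = failure or FailureModel()
        self._rng_fail = rng_failures or np.random.default_rng(0)
        self._rng_repair = rng_repairs or np.random.default_rng(1)
        self.round_durations = round_durations

        self.clock: int = 0
        self.machines = [MachineState(id=i) for i in range(n_machines)]
        self.queue: list[Patient] = []
        self.completed: list[Patient] = []
        self.patients: list[Patient] = []
        self._by_id: dict[int, Patient] = {}
        self.event_log: list[dict] = []

        self._arrivals = arr
        self._durations = dur
        self._priorities = pri
        self._next_arrival = 0
        self._admit_due()

    # -- inspection helpers -------------------------------------------------

    @property
    def n_machines(self) -> int:
        return len(self.machines)

    @property
    def n_arrived(self) -> int:
        return len(self.patients)

    @property
    def n_in_service(self) -> int:
        return sum(1 for m in self.machines if m.status == BUSY)

    def idle_machine_ids(self) -> list[int]:
        return [m.id for m in self.machines if m.status == IDLE]

    def total_busy_minutes(self) -> float:
        return sum(m.cumulative_busy for m in self.machines)

    def total_down_minutes(self) -> float:
        return sum(m.cumulative_down for m in self.machines)

    # -- operations ---------------------------------------------------------

    def assign(self, patient_id: int, machine_id: int) -> None:
        """Start the queued patient on an idle machine at the current clock."""
        if not (0 <= machine_id < self.n_machines):
            raise IllegalActionError(f"no machine {machine_id}")
        machine = self.machines[machine_id]
        if machine.status != IDLE:
            raise IllegalActionError(
                f"machine {machine_id} is {machine.status}, not idle"
            )
        idx = next(
            (i for i, p in enumerate(self.queue) if p.id == patient_id), None
        )
        if idx is None:
            raise IllegalActionError(f"patient {patient_id} is not in the queue")
        patient = self.queue.pop(idx)
        patient.start_time = float(self.clock)
        served = (
            float(math.ceil(patient.exam_duration))
            if self.round_durations
            else float(patient.exam_duration)
        )
        machine.status = BUSY
        machine.current_patient = patient.id
        machine.busy_until = self.clock + served
        self._log("start", patient=patient.id, machine=machine_id)

    def advance_one_minute(self) -> None:
        """Advance the clock one minute and resolve the tick's events."""
        hazard = self.failure.per_minute_hazard
        # Accrue the elapsing minute against each machine's current status.
        for m in self.machines:
            if m.status == BUSY:
                m.cumulative_busy += 1.0
            elif m.status == FAILED:
                m.cumulative_down += 1.0
        self.clock += 1
        t = self.clock
        # 1. Repairs complete.
        for m in self.machines:
            if m.status == FAILED and m.repair_until <= t:
                m.status = IDLE
                m.repair_until = None
                self._log("repaired", machine=m.id)
        # 2. Exams complete.
        for m in self.machines:
            if m.status == BUSY and m.busy_until <= t:
                patient = self._by_id[m.current_patient]
                patient.completion_time = float(m.busy_until)
                self.completed.append(patient)
                self._log("complete", patient=patient.id, machine=m.id)
                m.status = IDLE
                m.current_patient = None
                m.busy_until = None
        # 3. Failures strike machines still operating.
        for m in self.machines:
            if m.status == BUSY and self._rng_fail.random() < hazard:
                patient = self._by_id[m.current_patient]
                patient.start_time = None
                self.queue.insert(0, patient)  # head of queue, original arrival
                m.status = FAILED
                m.current_patient = None
                m.busy_until = None
                m.repair_until = t + sample_repair_duration(
                    self.failure, self._rng_repair
                )
                self._log("failure", patient=patient.id, machine=m.id)
        # 4. New arrivals join the queue.
        self._admit_due()

    # -- internals ----------------------------------------------------------

    def _admit_due(self) -> None:
        while (
            self._next_arrival < len(self._arrivals)
            and self._arrivals[self._next_arrival] <= self.clock
        ):
            i = self._next_arrival
            patient = Patient(
                id=i,
                arrival_time=float(self._arrivals[i]),
                priority=int(self._priorities[i]),
                exam_duration=float(self._durations[i]),
            )
            self.patients.append(patient)
            self._by_id[patient.id] = patient
            self.queue.append(patient)
            self._log("arrival", patient=patient.id)
            self._next_arrival += 1

    def _log(self, kind: str, patient: int | None = None, machine: int | None = None) -> None:
        self.event_log.append(
            {"time": self.clock, "type": kind, "patient": patient, "machine": machine}
        )


def write_event_log(twin: DigitalTwin, path: str) -> None:
    """Event log as JSONL: one ``{time, type, patient, machine}`` per line."""
    with open(path, "w") as fh:
        for event in twin.event_log:
            fh.write(json.dumps(event) + "\n")


def write_patient_table(twin: DigitalTwin, path: str) -> None:
    """Per-patient CSV: id, arrival, priority, start, completion, wait."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "arrival", "priority", "start", "completion", "wait"])
        for p in twin.patients:
            writer.writerow(
                [
                    p.id,
                    f"{p.arrival_time:.3f}",
                    p.priority,
                    "" if p.start_time is None else f"{p.start_time:.3f}",
                    "" if p.completion_time is None else f"{p.completion_time:.3f}",
                    "" if p.wait is None else f"{p.wait:.3f}",
                ]
            )
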