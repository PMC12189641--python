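"""Episodic decision environment over the digital twin.

One decision epoch per simulated minute: the agent either assigns one
visible queue slot to one idle machine or waits, then the twin advances a
minute.  Observations are fixed-length vectors (queue length, per-slot
wait/priority/presence features for the first K slots, per-machine status
one-hots); exam durations are never observable.

The per-step reward is  alpha*U(a) - beta*W(a) - delta*I(a)  with

* ``U(a)``: +1/k when the action starts an exam (instantaneous gain in the
  fraction of machines busy), 0 for wait;
* ``W(a)``: priority-weighted waiting incurred until the next decision,
  sum over patients still queued after the action of (1/P_i) * (1 min)/60;
* ``I(a)``: workload imbalance, the standard deviation of per-machine
  cumulative busy minutes divided by the elapsed clock (0 at clock 0).

``beta`` is shaped for congestion: beta0*(1 + rho*queue/K0) once the queue
exceeds the baseline length K0, else beta0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from . import twin as dt
from .calibration import PriorityMix, sample_priorities
from .twin import DigitalTwin, IllegalActionError

if TYPE_CHECKING:  # pragma: no cover
    from .config import ScenarioConfig

__all__ = [
    "RewardParams",
    "SchedulingAction",
    "EpisodeFinished",
    "shaped_beta",
    "observe",
    "legal_action_mask",
    "reward",
    "MriSchedulingEnv",
]

_STATUS_INDEX = {dt.IDLE: 0, dt.BUSY: 1, dt.FAILED: 2}


class EpisodeFinished(RuntimeError):
    """step() was called after the episode horizon was reached."""


@dataclass(frozen=True)
class RewardParams:
    """Weights of the composite scheduling reward.

    alpha rewards starting exams, beta0 penalizes priority-weighted
    waiting (scaled up by rho per unit of overload once the queue exceeds
    ``baseline_queue``), delta penalizes machine-workload imbalance, and
    gamma is the discount used by the learning agent.
    """

    alpha: float = 1.0
    beta0: float = 1.0
    delta: float = 0.1
    rho: float = 0.5
    baseline_queue: float = 10.0
    gamma: float = 0.9

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta0, self.delta) < 0:
            raise ValueError("alpha, beta0 and delta must be non-negative")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not self.baseline_queue > 0:
            raise ValueError("baseline_queue must be positive")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")


@dataclass(frozen=True)
class SchedulingAction:
    """Assign a visible queue slot to a machine, or wait one minute."""

    kind: str  # "assign" | "wait"
    slot_index: Optional[int] = None
    machine_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("assign", "wait"):
            raise ValueError("kind must be 'assign' or 'wait'")
        if self.kind == "assign" and (
            self.slot_index is None or self.machine_index is None
        ):
            raise ValueError("assign actions need slot and machine indices")

    @staticmethod
    def wait() -> "SchedulingAction":
        return SchedulingAction(kind="wait")

    @staticmethod
    def assign(slot_index: int, machine_index: int) -> "SchedulingAction":
        return SchedulingAction("assign", slot_index, machine_index)

    def to_index(self, n_machines: int, queue_window: int) -> int:
        if self.kind == "wait":
            return queue_window * n_machines
        return self.slot_index * n_machines + self.machine_index

    @staticmethod
    def from_index(index: int, n_machines: int, queue_window: int) -> "SchedulingAction":
        n_actions = queue_window * n_machines + 1
        if not (0 <= index < n_actions):
            raise ValueError(f"action index {index} outside [0, {n_actions})")
        if index == n_actions - 1:
            return SchedulingAction.wait()
        slot, machine = divmod(index, n_machines)
        return SchedulingAction.assign(slot, machine)


def shaped_beta(queue_length: int, params: RewardParams) -> float:
    """Congestion-shaped waiting weight.

    Returns beta0*(1 + rho*OverloadFactor) with OverloadFactor =
    queue_length / baseline_queue, but only when the overload factor
    strictly exceeds 1; at or below baseline the static beta0 applies.
    """
    if queue_length < 0:
        raise ValueError("queue_length must be non-negative")
    overload = queue_length / params.baseline_queue
    if overload > 1.0:
        return params.beta0 * (1.0 + params.rho * overload)
    return params.beta0


def observe(state: DigitalTwin, queue_window: int, wait_norm: float = 480.0) -> np.ndarray:
    """Fixed-length observation vector of length 1 + 5K + 3k.

    Entry 0 is the queue length scaled by 1/K; each of the K slots carries
    (wait/wait_norm, priority one-hot x3, presence flag); each machine a
    status one-hot (idle, busy, failed).  Empty slots are zero-filled.
    """
    k = state.n_machines
    vec = np.zeros(1 + 5 * queue_window + 3 * k, dtype=float)
    vec[0] = len(state.queue) / queue_window
    for s, patient in enumerate(state.queue[:queue_window]):
        base = 1 + 5 * s
        vec[base] = (state.clock - patient.arrival_time) / wait_norm
        vec[base + 1 + (patient.priority - 1)] = 1.0
        vec[base + 4] = 1.0
    machine_base = 1 + 5 * queue_window
    for j, m in enumerate(state.machines):
        vec[machine_base + 3 * j + _STATUS_INDEX[m.status]] = 1.0
    return vec


def legal_action_mask(state: DigitalTwin, queue_window: int) -> np.ndarray:
    """Boolean mask over the K*k+1 actions.

    (slot, machine) is legal iff the slot is occupied and the machine is
    idle; wait (the last index) is always legal.
    """
    k = state.n_machines
    mask = np.zeros(queue_window * k + 1, dtype=bool)
    idle = state.idle_machine_ids()
    if idle:
        for s in range(min(len(state.queue), queue_window)):
            for j in idle:
                mask[s * k + j] = True
    mask[-1] = True
    return mask


def reward(
    state_before: DigitalTwin,
    action: SchedulingAction,
    state_after: DigitalTwin,
    params: RewardParams,
) -> float:
    """Composite reward for taking ``action`` in ``state_before``.

    ``state_after`` is the state immediately after the action is applied
    (before the next minute elapses); the congestion-shaped beta is
    evaluated on the pre-action queue length.
    """
    k = state_after.n_machines
    u = (1.0 / k) if action.kind == "assign" else 0.0
    w = sum(1.0 / p.priority for p in state_after.queue) / 60.0
    busy = np.array([m.cumulative_busy for m in state_after.machines])
    imbalance = float(busy.std() / state_after.clock) if state_after.clock > 0 else 0.0
    beta = shaped_beta(len(state_before.queue), params)
    return params.alpha * u - beta * w - params.delta * imbalance


def _reward_after_action(
    queue_length_before: int,
    acted: bool,
    state_after: DigitalTwin,
    params: RewardParams,
) -> float:
    """Same computation as :func:`reward` but on the live (mutated) twin,
    with the pre-action queue length captured by the caller."""
    k = state_after.n_machines
    u = (1.0 / k) if acted else 0.0
    w = sum(1.0 / p.priority for p in state_after.queue) / 60.0
    busy = np.array([m.cumulative_busy for m in state_after.machines])
    imbalance = float(busy.std() / state_after.clock) if state_after.clock > 0 else 0.0
    beta = shaped_beta(queue_length_before, params)
    return params.alpha * u - beta * w - params.delta * imbalance


class MriSchedulingEnv:
    """reset/step environment over :class:`DigitalTwin`.

    ``reset(seed)`` derives independent sub-streams for arrivals, exam
    durations, priorities, failures and repairs from the one seed, so two
    policies evaluated with the same seed face identical exogenous
    realizations (common random numbers).
    """

    def __init__(self, scenario: "ScenarioConfig", horizon_minutes: int | None = None):
        self.scenario = scenario
        self.queue_window = scenario.queue_window
        self.n_machines = scenario.n_machines
        self.horizon = int(
            horizon_minutes
            if horizon_minutes is not None
            else scenario.episode_minutes
        )
        if self.horizon < 1:
            raise ValueError("horizon must be at least one minute")
        self.reward_params = scenario.reward
        self.wait_norm = scenario.wait_norm_minutes
        self.n_actions = self.queue_window * self.n_machines + 1
        self.wait_action = self.n_actions - 1
        self.obs_dim = 1 + 5 * self.queue_window + 3 * self.n_machines
        self._twin: DigitalTwin | None = None
        self._done = True
        self._n_assignments = 0

    # -- episode lifecycle --------------------------------------------------

    def reset(self, seed: int) -> tuple[np.ndarray, dict]:
        ss = np.random.SeedSequence(seed)
        s_arr, s_dur, s_pri, s_fail, s_rep = ss.spawn(5)
        scenario = self.scenario
        profile = scenario.rate_profile()
        arrivals = dt.sample_arrival_times(
            profile, self.horizon, np.random.default_rng(s_arr)
        )
        n = len(arrivals)
        rng_dur = np.random.default_rng(s_dur)
        if scenario.service_distribution == "exponential":
            durations = rng_dur.exponential(scenario.exp_service_mean_minutes, n)
            round_durations = False
        else:
            params = scenario.duration_params()
            durations = rng_dur.lognormal(params.mu, params.sigma, n)
            round_durations = True
        priorities = sample_priorities(
            PriorityMix(scenario.priority_mix), n, np.random.default_rng(s_pri)
        )
        self._twin = DigitalTwin(
            n_machines=self.n_machines,
            arrival_times=arrivals,
            durations=durations,
            priorities=priorities,
            failure=scenario.failure_model(),
            rng_failures=np.random.default_rng(s_fail),
            rng_repairs=np.random.default_rng(s_rep),
            round_durations=round_durations,
        )
        self._done = False
        self._n_assignments = 0
        return self.observe(), {"mask": self.legal_action_mask()}

    def step(self, action: int) -> tuple[np.ndarray, float, bool, dict]:
        if self._done or self._twin is None:
            raise EpisodeFinished("call reset() before stepping")
        action = int(action)
        mask = self.legal_action_mask()
        if not (0 <= action < self.n_actions) or not mask[action]:
            raise IllegalActionError(f"action {action} is illegal in this state")
        twin = self._twin
        queue_length_before = len(twin.queue)
        acted = action != self.wait_action
        if acted:
            slot, machine = divmod(action, self.n_machines)
            twin.assign(twin.queue[slot].id, machine)
            self._n_assignments += 1
        step_reward = _reward_after_action(
            queue_length_before, acted, twin, self.reward_params
        )
        twin.advance_one_minute()
        self._done = twin.clock >= self.horizon
        info = {
            "mask": self.legal_action_mask(),
            "clock": twin.clock,
            "n_assignments": self._n_assignments,
            "queue_length": len(twin.queue),
        }
        return self.observe(), step_reward, self._done, info

    # -- views --------------------------------------------------------------

    @property
    def twin(self) -> DigitalTwin:
        if self._twin is None:
            raise RuntimeError("environment has not been reset")
        return self._twin

    @property
    def done(self) -> bool:
        return self._done

    def observe(self) -> np.ndarray:
        return observe(self.twin, self.queue_window, self.wait_norm)

    def legal_action_mask(self) -> np.ndarray:
        return legal_action_mask(self.twin, self.queue_window)

    def action_from_index(self, index: int) -> SchedulingAction:
        return SchedulingAction.from_index(index, self.n_machines, self.queue_window)
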