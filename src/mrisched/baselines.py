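"""Reference scheduling policies.

All policies share one contract: ``policy(state, mask) -> action index``,
where ``state`` is the :class:`~mrisched.twin.DigitalTwin` and ``mask`` the
legal-action mask the environment exposes, so the evaluator is
policy-agnostic.  Baselines see the same K-slot queue window as the
learned agent.  Tie-breaks are deterministic: earliest arrival, then
patient id, and always the lowest-index idle machine.
"""

from __future__ import annotations

import numpy as np

from .twin import IDLE, DigitalTwin

__all__ = ["fcfs_policy", "static_priority_policy", "random_policy"]


def _geometry(state: DigitalTwin, mask: np.ndarray) -> tuple[int, int, int]:
    k = state.n_machines
    queue_window = (len(mask) - 1) // k
    wait_index = len(mask) - 1
    return k, queue_window, wait_index


def fcfs_policy(state: DigitalTwin, mask: np.ndarray) -> int:
    """First-come-first-served: earliest visible patient (slot 0) to the
    lowest-index idle machine; wait when nothing can be assigned."""
    k, _, wait_index = _geometry(state, mask)
    idle = state.idle_machine_ids()
    if state.queue and idle:
        return 0 * k + idle[0]
    return wait_index


def static_priority_policy(state: DigitalTwin, mask: np.ndarray) -> int:
    """Strict clinical urgency: the most urgent visible patient (lowest
    priority number; ties by arrival time then id) to the lowest-index idle
    machine, disregarding machine load balance."""
    k, queue_window, wait_index = _geometry(state, mask)
    idle = state.idle_machine_ids()
    visible = state.queue[:queue_window]
    if not visible or not idle:
        return wait_index
    slot = min(
        range(len(visible)),
        key=lambda s: (visible[s].priority, visible[s].arrival_time, visible[s].id),
    )
    return slot * k + idle[0]


def random_policy(
    state: DigitalTwin, mask: np.ndarray, rng: np.random.Generator
) -> int:
    """Uniform draw over the legal actions (testing aid)."""
    legal = np.flatnonzero(mask)
    return int(legal[rng.integers(legal.size)])
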