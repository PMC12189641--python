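"""Scenario runner: multi-seed policy evaluation, policy comparison tables
and the analytic queueing validation harness.

Every policy is evaluated under common random numbers — seed i yields the
same arrival, duration, priority, failure and repair streams for each
policy — so differences in the reported metrics reflect scheduling
decisions, not sampling luck.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import baselines, dqn
from .config import ScenarioConfig
from .env import MriSchedulingEnv
from .metrics import (
    MetricsReport,
    aggregate_runs,
    erlang_c_wait,
    fairness_index,
    mean_wait,
    utilization,
)
from .twin import DigitalTwin, FailureModel, sample_arrival_times
from .calibration import RateProfile

__all__ = [
    "FCFSPolicy",
    "StaticPriorityPolicy",
    "RandomPolicy",
    "DQNGreedyPolicy",
    "train_agent",
    "evaluate_policy",
    "report_from_twin",
    "run_scenario",
    "compare_policies",
    "percent_increase",
    "percent_reduction",
    "run_queueing_validation",
]


class FCFSPolicy:
    name = "fcfs"

    def act(self, env: MriSchedulingEnv) -> int:
        return baselines.fcfs_policy(env.twin, env.legal_action_mask())


class StaticPriorityPolicy:
    name = "static_priority"

    def act(self, env: MriSchedulingEnv) -> int:
        return baselines.static_priority_policy(env.twin, env.legal_action_mask())


class RandomPolicy:
    name = "random"

    def __init__(self, seed: int = 0) -> None:
        self._rng = np.random.default_rng(seed)

    def act(self, env: MriSchedulingEnv) -> int:
        return baselines.random_policy(env.twin, env.legal_action_mask(), self._rng)


class DQNGreedyPolicy:
    """Greedy (epsilon = 0) policy over a trained value network."""

    name = "dqn"

    def __init__(self, network: dqn.QNetwork) -> None:
        self.network = network

    def act(self, env: MriSchedulingEnv) -> int:
        return dqn.select_action(
            self.network, env.observe(), env.legal_action_mask(), epsilon=0.0
        )


def train_agent(scenario: ScenarioConfig) -> dqn.TrainResult:
    """Train the DQN agent on day-long training episodes of the scenario."""
    env = MriSchedulingEnv(scenario, horizon_minutes=scenario.episode_minutes)
    return dqn.train(env, scenario.agent)


def report_from_twin(
    twin: DigitalTwin, horizon_minutes: int, seed: int
) -> MetricsReport:
    """Summarize one finished run.  Waits cover patients whose exam started
    (including any still on a machine at the horizon); patients still
    queued are reported as censored."""
    served = [p for p in twin.patients if p.start_time is not None]
    waits = [p.wait for p in served]
    prios = [p.priority for p in served]
    util = utilization(twin.total_busy_minutes(), twin.n_machines * horizon_minutes)
    wbar = mean_wait(waits) if waits else float("nan")
    fair = fairness_index(waits, prios) if served else float("nan")
    per_priority = tuple(
        (
            float(np.mean([w for w, p in zip(waits, prios) if p == level]))
            if any(p == level for p in prios)
            else float("nan")
        )
        for level in (1, 2, 3)
    )
    return MetricsReport(
        utilization=util,
        mean_wait=wbar,
        fairness=fair,
        per_priority_wait=per_priority,
        n_served=len(served),
        n_arrived=twin.n_arrived,
        n_censored=len(twin.queue),
        seed=seed,
    )


def evaluate_policy(
    policy, scenario: ScenarioConfig, seed: int, horizon_minutes: int | None = None
) -> MetricsReport:
    """Run one policy over the full evaluation horizon for one seed."""
    horizon = horizon_minutes if horizon_minutes is not None else scenario.horizon_minutes
    env = MriSchedulingEnv(scenario, horizon_minutes=horizon)
    env.reset(seed)
    while not env.done:
        env.step(policy.act(env))
    return report_from_twin(env.twin, horizon, seed)


def run_scenario(policy, scenario: ScenarioConfig) -> list[MetricsReport]:
    """One report per seed (base_seed + i), deterministic and policy-order
    independent."""
    return [evaluate_policy(policy, scenario, seed) for seed in scenario.seeds()]


def percent_increase(a: float, b: float) -> float:
    """(a - b) / b * 100: how much larger a is than the reference b."""
    return (a - b) / b * 100.0


def percent_reduction(new: float, old: float) -> float:
    """(old - new) / old * 100: relative reduction from old down to new."""
    return (old - new) / old * 100.0


def compare_policies(
    scenario: ScenarioConfig, policies: Mapping[str, object]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate several policies under common random numbers.

    Returns a summary table (mean ± sd of U, W̄, F per policy) and a table
    of pairwise deltas: utilization and fairness as percent increases of a
    over b, waiting time as the percent reduction achieved by a relative
    to b.
    """
    if len(policies) < 2:
        raise ValueError("need at least two policies to compare")
    summaries = {}
    for name, policy in policies.items():
        reports = run_scenario(policy, scenario)
        summaries[name] = aggregate_runs(reports)
    rows = []
    for name, agg in summaries.items():
        rows.append(
            {
                "policy": name,
                "utilization_mean": agg["utilization"][0],
                "utilization_sd": agg["utilization"][1],
                "mean_wait_mean": agg["mean_wait"][0],
                "mean_wait_sd": agg["mean_wait"][1],
                "fairness_mean": agg["fairness"][0],
                "fairness_sd": agg["fairness"][1],
            }
        )
    summary = pd.DataFrame(rows).set_index("policy")
    deltas = []
    names = list(summaries)
    for a in names:
        for b in names:
            if a == b:
                continue
            deltas.append(
                {
                    "policy_a": a,
                    "policy_b": b,
                    "utilization_gain_pct": percent_increase(
                        summaries[a]["utilization"][0], summaries[b]["utilization"][0]
                    ),
                    "wait_reduction_pct": percent_reduction(
                        summaries[a]["mean_wait"][0], summaries[b]["mean_wait"][0]
                    ),
                    "fairness_gain_pct": percent_increase(
                        summaries[a]["fairness"][0], summaries[b]["fairness"][0]
                    ),
                }
            )
    return summary, pd.DataFrame(deltas)


def run_queueing_validation(
    lam_per_hour: float = 1.0,
    mean_service_minutes: float = 120.0,
    c: int = 3,
    horizon_minutes: int = 200_000,
    seed: int = 0,
    warmup_minutes: int = 5000,
    n_batches: int = 20,
) -> dict:
    """M/M/c validation run: exponential service, no failures, greedy FCFS.

    Returns the simulated mean queue wait, a batch-means Monte-Carlo
    standard error, the Erlang-C prediction, and both sides of Little's
    law (time-average queue length vs measured arrival rate x mean wait).
    Assignments are repeated within a minute until no idle machine faces a
    non-empty queue, so the discipline is plain FCFS rather than the
    one-assignment-per-minute decision process.  The default configuration
    uses services long relative to the one-minute tick so that
    discretization bias stays far below the Monte-Carlo error, and batches
    much longer than the waiting-time correlation time so the batch-means
    standard error is honest.
    """
    ss = np.random.SeedSequence(seed)
    s_arr, s_dur = ss.spawn(2)
    profile = RateProfile((float(lam_per_hour),) * 24)
    arrivals = sample_arrival_times(
        profile, horizon_minutes, np.random.default_rng(s_arr)
    )
    durations = np.random.default_rng(s_dur).exponential(
        mean_service_minutes, len(arrivals)
    )
    twin = DigitalTwin(
        n_machines=c,
        arrival_times=arrivals,
        durations=durations,
        priorities=np.ones(len(arrivals), dtype=int),
        failure=FailureModel(p_fail_per_hour=0.0, mean_repair_hours=1.0),
        round_durations=False,
    )
    queue_sum = 0
    queue_samples = 0
    while twin.clock < horizon_minutes:
        idle = twin.idle_machine_ids()
        while twin.queue and idle:
            twin.assign(twin.queue[0].id, idle.pop(0))
        if twin.clock >= warmup_minutes:
            queue_sum += len(twin.queue)
            queue_samples += 1
        twin.advance_one_minute()

    waits = np.asarray(
        [
            p.wait
            for p in twin.patients
            if p.start_time is not None and p.arrival_time >= warmup_minutes
        ]
    )
    n_window_arrivals = sum(1 for p in twin.patients if p.arrival_time >= warmup_minutes)
    window = horizon_minutes - warmup_minutes
    sim_wait = float(waits.mean())
    batches = np.array_split(waits, n_batches)
    batch_means = np.asarray([b.mean() for b in batches if len(b)])
    se = float(batch_means.std(ddof=1) / np.sqrt(len(batch_means)))
    lam_per_min = lam_per_hour / 60.0
    theory = erlang_c_wait(lam_per_min, 1.0 / mean_service_minutes, c)
    lam_hat = n_window_arrivals / window
    mean_queue_len = queue_sum / queue_samples
    return {
        "sim_mean_wait": sim_wait,
        "wait_se": se,
        "erlang_c_wait": theory,
        "mean_queue_length": mean_queue_len,
        "littles_rhs": lam_hat * sim_wait,
        "lam_hat_per_min": lam_hat,
        "n_waits": int(waits.size),
    }
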