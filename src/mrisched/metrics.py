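"""Performance metrics and analytic queueing oracles.

Three headline metrics summarize a simulated horizon:

* utilization ``U`` = total busy machine-minutes / total available
  machine-minutes (downtime counts as available, so failures depress U);
* mean wait ``W̄`` = average minutes from arrival to exam start over
  patients whose exam started (patients still waiting at the horizon are
  censored out and reported as a count);
* priority-weighted fairness ``F``: Jain's index on x_i = W_i / P_i, i.e.
  ``(Σx)² / (n·Σx²)``, equal to 1 when weighted waits are perfectly even
  and 1/n under maximal inequality.  The all-zero-wait case (a 0/0 form)
  is defined as 1.

The Erlang-C closed form supplies an independent M/M/c waiting-time oracle
for validating the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MetricsReport",
    "utilization",
    "mean_wait",
    "fairness_index",
    "erlang_c_wait",
    "aggregate_runs",
]


@dataclass(frozen=True)
class MetricsReport:
    """Metrics of one simulated run (one seed)."""

    utilization: float
    mean_wait: float
    fairness: float
    per_priority_wait: tuple[float, float, float]
    n_served: int
    n_arrived: int
    n_censored: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "utilization": self.utilization,
            "mean_wait": self.mean_wait,
            "fairness": self.fairness,
            "per_priority_wait": list(self.per_priority_wait),
            "n_served": self.n_served,
            "n_arrived": self.n_arrived,
            "n_censored": self.n_censored,
            "seed": self.seed,
        }


def utilization(total_busy: float, total_available: float) -> float:
    """Fraction of available machine-minutes spent scanning."""
    if total_available <= 0:
        raise ValueError("total_available must be positive")
    if total_busy < 0 or total_busy > total_available * (1 + 1e-12):
        raise ValueError("total_busy must lie in [0, total_available]")
    return min(total_busy / total_available, 1.0)


def mean_wait(waits: Iterable[float]) -> float:
    """Arithmetic mean waiting time in minutes."""
    arr = np.asarray(list(waits), dtype=float)
    if arr.size == 0:
        raise ValueError("mean wait is undefined on an empty sample")
    if np.any(arr < 0):
        raise ValueError("waits must be non-negative")
    return float(arr.mean())


def fairness_index(waits: Iterable[float], priorities: Iterable[int]) -> float:
    """Priority-weighted Jain fairness on x_i = W_i / P_i, in [1/n, 1]."""
    w = np.asarray(list(waits), dtype=float)
    p = np.asarray(list(priorities), dtype=float)
    if w.size == 0 or w.shape != p.shape:
        raise ValueError("need equal-length, non-empty waits and priorities")
    if np.any(w < 0):
        raise ValueError("waits must be non-negative")
    if not np.all(np.isin(p, (1, 2, 3))):
        raise ValueError("priorities must be 1, 2 or 3")
    x = w / p
    sum_sq = float((x**2).sum())
    if sum_sq == 0.0:
        return 1.0  # all weighted waits zero: perfectly equal
    total = float(x.sum())
    return total * total / (x.size * sum_sq)


def erlang_c_wait(lam: float, mu: float, c: int) -> float:
    """Expected M/M/c queue wait (same time unit as the rates).

    ``lam`` is the arrival rate, ``mu`` the per-server service rate and
    ``c`` the server count; requires stability lam < c*mu.
    """
    if c < 1:
        raise ValueError("need at least one server")
    if mu <= 0 or lam < 0:
        raise ValueError("rates must be positive (lam may be 0)")
    if lam == 0:
        return 0.0
    if not lam < c * mu:
        raise ValueError("unstable system: need lam < c*mu")
    a = lam / mu
    rho = a / c
    # Erlang-B by the standard recurrence, then convert to Erlang-C.
    blocking = 1.0
    for i in range(1, c + 1):
        blocking = a * blocking / (i + a * blocking)
    prob_wait = blocking / (1.0 - rho * (1.0 - blocking))
    return prob_wait / (c * mu - lam)


def aggregate_runs(
    reports: Sequence[MetricsReport],
) -> dict[str, tuple[float, float]]:
    """Per-metric mean and sample sd (ddof=1; 0 for a single run) across
    seeds, mirroring a mean ± sd results table."""
    if len(reports) == 0:
        raise ValueError("need at least one report")

    def stats(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    return {
        "utilization": stats([r.utilization for r in reports]),
        "mean_wait": stats([r.mean_wait for r in reports]),
        "fairness": stats([r.fairness for r in reports]),
    }
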