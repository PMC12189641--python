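"""Stochastic calibration of the MRI-suite digital twin.

The twin needs three stochastic ingredients: a diurnal arrival-rate profile
for the non-homogeneous Poisson arrival process, log-normal scan-duration
parameters, and a three-level clinical priority mix (1 = urgent,
2 = semi-urgent, 3 = elective).  Real installations would estimate these
from scheduler logs or scan metadata; this module ships a synthetic
stand-in generator with the same positive-skew duration shape, plus a
maximum-likelihood fitter for user-supplied duration tables.

All shipped defaults are calibration stand-ins (clearly overridable via the
scenario config): median scan 30 min with log-sd 0.4, daytime peak of
4 patients/h against an off-peak trickle of 0.5/h, and a 10/30/60
urgent/semi-urgent/elective mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SIGMA_FLOOR",
    "DEFAULT_DURATION_MU",
    "DEFAULT_DURATION_SIGMA",
    "DEFAULT_PRIORITY_MIX",
    "LogNormalParams",
    "RateProfile",
    "PriorityMix",
    "fit_lognormal",
    "generate_synthetic_scan_records",
    "default_diurnal_profile",
    "sample_priority",
    "sample_priorities",
]

#: Lower bound on the fitted log-sd so downstream sampling stays well defined
#: on degenerate (all-equal) inputs.
SIGMA_FLOOR = 1e-6

#: Stand-in duration calibration: median scan of 30 minutes.
DEFAULT_DURATION_MU = math.log(30.0)
DEFAULT_DURATION_SIGMA = 0.4

#: Stand-in urgent / semi-urgent / elective shares.
DEFAULT_PRIORITY_MIX = (0.10, 0.30, 0.60)

#: Daytime peak window, hour-of-day bins [8, 17).
PEAK_HOURS = tuple(range(8, 17))


@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal scan-duration parameters, both in log-minutes."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be a positive real")

    @property
    def median_minutes(self) -> float:
        return math.exp(self.mu)

    @property
    def mean_minutes(self) -> float:
        return math.exp(self.mu + 0.5 * self.sigma**2)


@dataclass(frozen=True)
class RateProfile:
    """Piecewise-constant arrival intensity λ(t) in patients per hour.

    ``hourly_rates`` holds one rate per hour-of-day; ``weekly_multipliers``
    one factor per day-of-week (Monday = index 0), defaulting to flat weeks.
    An all-zero profile is legal and simply produces no arrivals.
    """

    hourly_rates: tuple[float, ...]
    weekly_multipliers: tuple[float, ...] = (1.0,) * 7

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.hourly_rates)
        mults = tuple(float(m) for m in self.weekly_multipliers)
        if len(rates) != 24:
            raise ValueError("need exactly 24 hourly rates")
        if len(mults) != 7:
            raise ValueError("need exactly 7 weekly multipliers")
        if any(not np.isfinite(r) or r < 0 for r in rates):
            raise ValueError("hourly rates must be non-negative reals")
        if any(not np.isfinite(m) or m < 0 for m in mults):
            raise ValueError("weekly multipliers must be non-negative reals")
        object.__setattr__(self, "hourly_rates", rates)
        object.__setattr__(self, "weekly_multipliers", mults)

    def rate_at(self, minute: float) -> float:
        """Intensity (patients/hour) at an absolute simulation minute."""
        if minute < 0:
            raise ValueError("minute must be non-negative")
        hour = int(minute // 60) % 24
        day = int(minute // 1440) % 7
        return self.hourly_rates[hour] * self.weekly_multipliers[day]

    @property
    def max_rate(self) -> float:
        """Upper bound on λ(t), used as the thinning envelope."""
        return max(self.hourly_rates) * max(self.weekly_multipliers)

    def expected_count(self, horizon_minutes: float) -> float:
        """∫λ(t)dt over [0, horizon), in expected patients."""
        if horizon_minutes < 0:
            raise ValueError("horizon must be non-negative")
        total = 0.0
        t = 0.0
        while t < horizon_minutes:
            step = min(60.0 - (t % 60.0), horizon_minutes - t)
            total += self.rate_at(t) * step / 60.0
            t += step
        return total


@dataclass(frozen=True)
class PriorityMix:
    """Categorical distribution over priority levels (1, 2, 3)."""

    probabilities: tuple[float, float, float] = DEFAULT_PRIORITY_MIX

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probabilities)
        if len(probs) != 3:
            raise ValueError("need exactly 3 priority probabilities")
        if any(not np.isfinite(p) or p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 (tolerance 1e-9)")
        object.__setattr__(self, "probabilities", probs)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.probabilities)


def fit_lognormal(durations: Iterable[float]) -> LogNormalParams:
    """Maximum-likelihood log-normal fit to scan durations in minutes.

    ``mu`` is the mean of the log-durations and ``sigma`` their population
    (ddof=0) standard deviation, floored at :data:`SIGMA_FLOOR`.

    Raises ``ValueError`` for fewer than two samples or any non-positive
    duration.
    """
    arr = np.asarray(list(durations), dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least 2 durations")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("durations must be strictly positive and finite")
    logs = np.log(arr)
    mu = float(logs.mean())
    sigma = float(max(logs.std(ddof=0), SIGMA_FLOOR))
    return LogNormalParams(mu=mu, sigma=sigma)


def generate_synthetic_scan_records(
    n: int,
    params: LogNormalParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` i.i.d. synthetic scan durations (minutes), seeded.

    Emulates the positive skew of real scan-duration metadata; used both
    as the shipped calibration stand-in and as a fixture source in tests.
    """
    if int(n) < 1:
        raise ValueError("n must be a positive integer")
    if params is None:
        params = LogNormalParams(DEFAULT_DURATION_MU, DEFAULT_DURATION_SIGMA)
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=params.mu, sigma=params.sigma, size=int(n))


def default_diurnal_profile(peak_rate: float, offpeak_rate: float) -> RateProfile:
    """Two-level diurnal profile: ``peak_rate`` during [08:00, 17:00),
    ``offpeak_rate`` otherwise, flat across the week."""
    if not (np.isfinite(peak_rate) and peak_rate > 0):
        raise ValueError("peak_rate must be > 0")
    if not (np.isfinite(offpeak_rate) and offpeak_rate >= 0):
        raise ValueError("offpeak_rate must be >= 0")
    if offpeak_rate > peak_rate:
        raise ValueError("offpeak_rate must not exceed peak_rate")
    rates = tuple(
        float(peak_rate) if h in PEAK_HOURS else float(offpeak_rate)
        for h in range(24)
    )
    return RateProfile(hourly_rates=rates)


def sample_priority(mix: PriorityMix, rng: np.random.Generator) -> int:
    """One categorical draw from the priority mix, returning 1, 2 or 3."""
    return int(np.searchsorted(mix.cumulative, rng.random(), side="right")) + 1


def sample_priorities(mix: PriorityMix, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vector of ``n`` priority draws (values in {1, 2, 3})."""
    if n < 0:
        raise ValueError("n must be non-negative")
    u = rng.random(int(n))
    return np.searchsorted(mix.cumulative, u, side="right").astype(np.int64) + 1
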