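"""Scenario configuration: every simulation, calibration, reward and agent
parameter of one experiment, serializable to YAML or JSON.

Defaults mirror the reference experiment: three machines over 30 simulated
days, diurnal arrivals peaking in [08:00, 17:00), log-normal scan
durations, a 10/30/60 urgent/semi-urgent/elective mix, breakdowns at 0.01
per operating hour with 3 h mean repairs, and metrics averaged over 10
seeds.  ``quick_scenario`` shrinks this to a desk-scale variant (5 days,
3 seeds, reduced training) used by the fast comparison suite.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import (
    DEFAULT_DURATION_MU,
    DEFAULT_DURATION_SIGMA,
    DEFAULT_PRIORITY_MIX,
    LogNormalParams,
    PriorityMix,
    RateProfile,
    default_diurnal_profile,
)
from .dqn import DQNConfig
from .env import RewardParams
from .twin import FailureModel

__all__ = ["ScenarioConfig", "quick_scenario"]


@dataclass(frozen=True)
class ScenarioConfig:
    n_machines: int = 3
    horizon_days: int = 30
    episode_minutes: int = 1440
    queue_window: int = 10
    peak_rate: float = 4.0
    offpeak_rate: float = 0.5
    hourly_rates: tuple[float, ...] | None = None
    weekly_multipliers: tuple[float, ...] = (1.0,) * 7
    duration_mu: float = DEFAULT_DURATION_MU
    duration_sigma: float = DEFAULT_DURATION_SIGMA
    priority_mix: tuple[float, float, float] = DEFAULT_PRIORITY_MIX
    p_fail_per_hour: float = 0.01
    mean_repair_hours: float = 3.0
    #: "lognormal" is the production mode; "exponential" is the validation
    #: mode used only for analytic queueing checks.
    service_distribution: str = "lognormal"
    exp_service_mean_minutes: float = 30.0
    wait_norm_minutes: float = 480.0
    reward: RewardParams = field(default_factory=RewardParams)
    agent: DQNConfig = field(default_factory=DQNConfig)
    n_seeds: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_machines < 1:
            raise ValueError("n_machines must be >= 1")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.queue_window < 1:
            raise ValueError("queue_window must be >= 1")
        if self.service_distribution not in ("lognormal", "exponential"):
            raise ValueError("service_distribution must be lognormal or exponential")
        if self.hourly_rates is not None:
            object.__setattr__(
                self, "hourly_rates", tuple(float(r) for r in self.hourly_rates)
            )
        object.__setattr__(
            self,
            "weekly_multipliers",
            tuple(float(m) for m in self.weekly_multipliers),
        )
        object.__setattr__(
            self, "priority_mix", tuple(float(p) for p in self.priority_mix)
        )
        # Fail fast on inconsistent component parameters.
        self.rate_profile()
        self.duration_params()
        PriorityMix(self.priority_mix)
        self.failure_model()

    # -- derived component objects ------------------------------------------

    def rate_profile(self) -> RateProfile:
        if self.hourly_rates is not None:
            return RateProfile(self.hourly_rates, self.weekly_multipliers)
        profile = default_diurnal_profile(self.peak_rate, self.offpeak_rate)
        return RateProfile(profile.hourly_rates, self.weekly_multipliers)

    def duration_params(self) -> LogNormalParams:
        return LogNormalParams(self.duration_mu, self.duration_sigma)

    def failure_model(self) -> FailureModel:
        return FailureModel(self.p_fail_per_hour, self.mean_repair_hours)

    @property
    def horizon_minutes(self) -> int:
        return self.horizon_days * 1440

    def seeds(self) -> list[int]:
        """Per-run seeds, derived as base_seed + i so any single run can be
        re-executed in isolation."""
        return [self.base_seed + i for i in range(self.n_seeds)]

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["reward"] = dataclasses.asdict(self.reward)
        agent = dataclasses.asdict(self.agent)
        agent["hidden"] = list(self.agent.hidden)
        raw["agent"] = agent
        raw["hourly_rates"] = (
            None if self.hourly_rates is None else list(self.hourly_rates)
        )
        raw["weekly_multipliers"] = list(self.weekly_multipliers)
        raw["priority_mix"] = list(self.priority_mix)
        return raw

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        data = dict(raw)
        if "reward" in data and isinstance(data["reward"], dict):
            data["reward"] = RewardParams(**data["reward"])
        if "agent" in data and isinstance(data["agent"], dict):
            agent = dict(data["agent"])
            if "hidden" in agent:
                agent["hidden"] = tuple(agent["hidden"])
            data["agent"] = DQNConfig(**agent)
        return cls(**data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw)

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)


def quick_scenario(**overrides) -> ScenarioConfig:
    """Desk-scale comparison scenario: 3 machines, 5 days, 3 seeds and a
    reduced training budget, with all stochastic calibration unchanged."""
    base = dict(
        horizon_days=5,
        n_seeds=3,
        agent=DQNConfig(train_steps=40_000, warmup_steps=1000),
    )
    base.update(overrides)
    return ScenarioConfig(**base)
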