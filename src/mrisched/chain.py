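"""Two-state deterministic chain MDP, a diagnostic environment for the
DQN training loop.

State 0 pays a small reward (0.05) for staying put; state 1 pays 0.5 for
staying.  Moving costs nothing and toggles the state.  At discount 0.5 the
optimal policy is to move from state 0 and stay in state 1, with exact
action values

    Q*(0, stay) = 0.3    Q*(0, move) = 0.5
    Q*(1, stay) = 1.0    Q*(1, move) = 0.25

all on unit scale, so learned Q-values can be compared to a value-
iteration oracle at tight tolerance.  Episodes are pure time-limit
truncations (``done`` is never True), so targets keep bootstrapping and
the learned values approximate the infinite-horizon fixed point.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ChainMDP"]


class ChainMDP:
    """reset/step environment matching the contract of
    :func:`mrisched.dqn.train`."""

    #: rewards[s][a] for actions (0 = stay, 1 = move)
    rewards = ((0.05, 0.0), (0.5, 0.0))
    #: successor[s][a]
    transitions = ((0, 1), (1, 0))
    #: discount under which the docstring's Q* values are exact
    gamma = 0.5

    n_states = 2
    n_actions = 2
    obs_dim = 2

    def __init__(self, horizon: int = 200) -> None:
        if horizon < 1:
            raise ValueError("horizon must be positive")
        self.horizon = horizon
        self._state = 0
        self._steps = 0

    def _observe(self) -> np.ndarray:
        obs = np.zeros(self.obs_dim)
        obs[self._state] = 1.0
        return obs

    @staticmethod
    def _mask() -> np.ndarray:
        return np.ones(2, dtype=bool)

    def reset(self, seed: int | None = None) -> tuple[np.ndarray, dict]:
        self._state = 0
        self._steps = 0
        return self._observe(), {"mask": self._mask()}

    def step(self, action: int) -> tuple[np.ndarray, float, bool, dict]:
        if action not in (0, 1):
            raise ValueError("action must be 0 or 1")
        reward = self.rewards[self._state][action]
        self._state = self.transitions[self._state][action]
        self._steps += 1
        truncated = self._steps >= self.horizon
        info = {"mask": self._mask(), "truncated": truncated}
        return self._observe(), reward, False, info
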