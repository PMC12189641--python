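"""Deep Q-Network scheduling agent.

A small fully connected value network (two tanh hidden layers of 128 by
default) maps observations to one Q-value per action.  Training follows
the standard DQN recipe: epsilon-greedy rollouts with a linear epsilon
decay from 1.0 to 0.01, a uniform-sampling ring replay buffer of up to
1e5 transitions, squared temporal-difference loss against a target
network, and a hard online-to-target parameter sync every
``target_update_every`` steps.  Illegal actions are masked to -inf both
when acting and inside the bootstrap max.

The network and its Adam optimizer are implemented directly on numpy
arrays; at these layer sizes that trains a scheduling policy in seconds
on a single CPU core and keeps runs bit-reproducible under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "DQNConfig",
    "QNetwork",
    "ReplayBuffer",
    "Batch",
    "TrainResult",
    "epsilon_at",
    "select_action",
    "td_targets",
    "train",
    "greedy_policy",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class DQNConfig:
    """Hyperparameters of the DQN training loop.

    ``epsilon_decay_steps`` defaults (when None) to 80% of ``train_steps``;
    exploration then stays at ``epsilon_end`` for the remaining steps.
    """

    hidden: tuple[int, ...] = (128, 128)
    learning_rate: float = 5e-4
    batch_size: int = 64
    buffer_capacity: int = 100_000
    target_update_every: int = 1000
    epsilon_start: float = 1.0
    epsilon_end: float = 0.01
    epsilon_decay_steps: Optional[int] = None
    gamma: float = 0.9
    train_steps: int = 200_000
    warmup_steps: int = 1000
    grad_clip: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.epsilon_start >= self.epsilon_end >= 0.0):
            raise ValueError("need epsilon_start >= epsilon_end >= 0")
        if self.target_update_every < 1:
            raise ValueError("target_update_every must be >= 1")
        if self.buffer_capacity < 1 or self.batch_size < 1:
            raise ValueError("buffer and batch sizes must be positive")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        if self.train_steps < 1:
            raise ValueError("train_steps must be positive")
        if self.epsilon_decay_steps is not None and self.epsilon_decay_steps < 0:
            raise ValueError("epsilon_decay_steps must be non-negative")

    @property
    def effective_decay_steps(self) -> int:
        if self.epsilon_decay_steps is not None:
            return self.epsilon_decay_steps
        return max(1, int(0.8 * self.train_steps))


def epsilon_at(step: int, config: DQNConfig) -> float:
    """Linearly decayed exploration rate at a (0-based) training step."""
    if step < 0:
        raise ValueError("step must be non-negative")
    decay = config.effective_decay_steps
    if decay == 0 or step >= decay:
        return config.epsilon_end
    frac = step / decay
    return config.epsilon_start + (config.epsilon_end - config.epsilon_start) * frac


class QNetwork:
    """Fully connected Q-value network with tanh hidden activations."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        hidden: tuple[int, ...] = (128, 128),
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.hidden = tuple(hidden)
        sizes = [in_dim, *hidden, out_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (a + b))  # Glorot-uniform
            self.weights.append(rng.uniform(-limit, limit, size=(a, b)))
            self.biases.append(np.zeros(b))

    # -- inference ----------------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        activations = [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ w + b)
            activations.append(h)
        q = h @ self.weights[-1] + self.biases[-1]
        return q, activations

    def q_values(self, x: np.ndarray) -> np.ndarray:
        """Q-values for a batch (B, in_dim) or single (in_dim,) observation."""
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        q, _ = self._forward(x)
        return q[0] if squeeze else q

    # -- training -----------------------------------------------------------

    def loss_and_gradients(
        self, obs: np.ndarray, actions: np.ndarray, targets: np.ndarray
    ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
        """Mean squared TD error on the chosen actions, with gradients."""
        q, activations = self._forward(obs)
        batch = np.arange(len(obs))
        err = q[batch, actions] - targets
        loss = float(np.mean(err**2))
        d_q = np.zeros_like(q)
        d_q[batch, actions] = 2.0 * err / len(obs)
        grad_w = [np.empty(0)] * len(self.weights)
        grad_b = [np.empty(0)] * len(self.biases)
        grad_w[-1] = activations[-1].T @ d_q
        grad_b[-1] = d_q.sum(axis=0)
        upstream = d_q @ self.weights[-1].T
        for i in range(len(self.weights) - 2, -1, -1):
            d_z = upstream * (1.0 - activations[i + 1] ** 2)  # tanh'
            grad_w[i] = activations[i].T @ d_z
            grad_b[i] = d_z.sum(axis=0)
            upstream = d_z @ self.weights[i].T
        return loss, grad_w, grad_b

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def copy_from(self, other: "QNetwork") -> None:
        for dst, src in zip(self.parameters(), other.parameters()):
            dst[...] = src

    def clone(self) -> "QNetwork":
        twin = QNetwork(self.in_dim, self.out_dim, self.hidden)
        twin.copy_from(self)
        return twin


class Adam:
    """Adam optimizer with global-norm gradient clipping."""

    def __init__(self, net: QNetwork, lr: float, grad_clip: float = 10.0) -> None:
        self.net = net
        self.lr = lr
        self.grad_clip = grad_clip
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        params = net.parameters()
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, obs: np.ndarray, actions: np.ndarray, targets: np.ndarray) -> float:
        loss, grad_w, grad_b = self.net.loss_and_gradients(obs, actions, targets)
        grads = grad_w + grad_b
        if self.grad_clip and self.grad_clip > 0:
            norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if norm > self.grad_clip:
                grads = [g * (self.grad_clip / norm) for g in grads]
        self.t += 1
        bias1 = 1.0 - self.beta1**self.t
        bias2 = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.net.parameters(), grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g**2
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
        return loss


@dataclass
class Batch:
    """A minibatch of replayed transitions."""

    obs: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    next_obs: np.ndarray
    dones: np.ndarray
    next_masks: np.ndarray


class ReplayBuffer:
    """Fixed-capacity ring buffer of transitions with uniform sampling."""

    def __init__(self, capacity: int, obs_dim: int, n_actions: int) -> None:
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._obs = np.zeros((capacity, obs_dim))
        self._actions = np.zeros(capacity, dtype=np.int64)
        self._rewards = np.zeros(capacity)
        self._next_obs = np.zeros((capacity, obs_dim))
        self._dones = np.zeros(capacity, dtype=bool)
        self._next_masks = np.zeros((capacity, n_actions), dtype=bool)
        self._size = 0
        self._cursor = 0

    def __len__(self) -> int:
        return self._size

    def add(
        self,
        obs: np.ndarray,
        action: int,
        reward: float,
        next_obs: np.ndarray,
        done: bool,
        next_mask: np.ndarray,
    ) -> None:
        i = self._cursor
        self._obs[i] = obs
        self._actions[i] = action
        self._rewards[i] = reward
        self._next_obs[i] = next_obs
        self._dones[i] = done
        self._next_masks[i] = next_mask
        self._cursor = (i + 1) % self.capacity
        self._size = min(self._size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator) -> Batch:
        if self._size == 0:
            raise ValueError("cannot sample from an empty buffer")
        idx = rng.integers(0, self._size, size=batch_size)
        return Batch(
            obs=self._obs[idx],
            actions=self._actions[idx],
            rewards=self._rewards[idx],
            next_obs=self._next_obs[idx],
            dones=self._dones[idx],
            next_masks=self._next_masks[idx],
        )


def select_action(
    net: QNetwork,
    obs: np.ndarray,
    mask: np.ndarray,
    epsilon: float,
    rng: np.random.Generator | None = None,
) -> int:
    """Epsilon-greedy action over the legal set; greedy ties go to the
    lowest index.  ``rng`` may be omitted when epsilon is 0."""
    legal = np.flatnonzero(mask)
    if legal.size == 0:
        raise ValueError("mask admits no legal action")
    if epsilon > 0:
        if rng is None:
            raise ValueError("epsilon > 0 requires an rng")
        if rng.random() < epsilon:
            return int(legal[rng.integers(legal.size)])
    q = net.q_values(obs)
    q = np.where(mask, q, -np.inf)
    return int(np.argmax(q))


def td_targets(batch: Batch, target_net: QNetwork, gamma: float) -> np.ndarray:
    """Bootstrapped targets r + gamma * max over legal a' of Q_target(s', a');
    terminal transitions use the bare reward."""
    q_next = target_net.q_values(batch.next_obs)
    q_next = np.where(batch.next_masks, q_next, -np.inf)
    max_next = q_next.max(axis=1)
    max_next = np.where(np.isfinite(max_next), max_next, 0.0)
    return batch.rewards + gamma * np.where(batch.dones, 0.0, max_next)


@dataclass
class TrainResult:
    """Trained network plus the training trace."""

    network: QNetwork
    config: DQNConfig
    episode_returns: list[float] = field(default_factory=list)
    episode_mean_epsilons: list[float] = field(default_factory=list)
    episode_mean_losses: list[float] = field(default_factory=list)
    sync_steps: list[int] = field(default_factory=list)

    def policy(self) -> Callable[[np.ndarray, np.ndarray], int]:
        return greedy_policy(self.network)

    def write_log(self, path: str) -> None:
        """Training log CSV: episode, return, mean epsilon, mean loss."""
        with open(path, "w") as fh:
            fh.write("# optimizer=adam grad_clip={} lr={} seed={}\n".format(
                self.config.grad_clip, self.config.learning_rate, self.config.seed
            ))
            fh.write("episode,return,mean_epsilon,mean_loss\n")
            rows = zip(
                self.episode_returns,
                self.episode_mean_epsilons,
                self.episode_mean_losses,
            )
            for i, (ret, eps, loss) in enumerate(rows):
                fh.write(f"{i},{ret:.6f},{eps:.6f},{loss:.6f}\n")


def train(env, config: DQNConfig) -> TrainResult:
    """Run the DQN training loop against a reset/step environment.

    The environment contract: ``reset(seed) -> (obs, info)`` and
    ``step(action) -> (obs, reward, done, info)`` with ``info['mask']`` the
    legal-action mask and an optional ``info['truncated']`` flag marking
    time-limit resets that should still bootstrap.  All randomness
    (network init, exploration, replay sampling, per-episode environment
    seeds) derives from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    s_init, s_act, s_sample, s_env = ss.spawn(4)
    net = QNetwork(env.obs_dim, env.n_actions, config.hidden, np.random.default_rng(s_init))
    target = net.clone()
    optimizer = Adam(net, config.learning_rate, config.grad_clip)
    buffer = ReplayBuffer(config.buffer_capacity, env.obs_dim, env.n_actions)
    rng_act = np.random.default_rng(s_act)
    rng_sample = np.random.default_rng(s_sample)
    rng_env = np.random.default_rng(s_env)

    result = TrainResult(network=net, config=config)

    def fresh_episode():
        seed = int(rng_env.integers(0, 2**31))
        obs, info = env.reset(seed)
        return obs, info["mask"]

    obs, mask = fresh_episode()
    ep_return = 0.0
    ep_epsilons: list[float] = []
    ep_losses: list[float] = []
    min_fill = max(config.warmup_steps, config.batch_size)

    for step in range(1, config.train_steps + 1):
        eps = epsilon_at(step - 1, config)
        action = select_action(net, obs, mask, eps, rng_act)
        next_obs, step_reward, done, info = env.step(action)
        next_mask = info["mask"]
        truncated = bool(info.get("truncated", False))
        buffer.add(obs, action, step_reward, next_obs, done and not truncated, next_mask)
        ep_return += step_reward
        ep_epsilons.append(eps)

        if len(buffer) >= min_fill:
            batch = buffer.sample(config.batch_size, rng_sample)
            targets = td_targets(batch, target, config.gamma)
            ep_losses.append(optimizer.step(batch.obs, batch.actions, targets))

        if step % config.target_update_every == 0:
            target.copy_from(net)
            result.sync_steps.append(step)

        if done or truncated:
            result.episode_returns.append(ep_return)
            result.episode_mean_epsilons.append(float(np.mean(ep_epsilons)))
            result.episode_mean_losses.append(
                float(np.mean(ep_losses)) if ep_losses else float("nan")
            )
            obs, mask = fresh_episode()
            ep_return = 0.0
            ep_epsilons, ep_losses = [], []
        else:
            obs, mask = next_obs, next_mask

    return result


def greedy_policy(net: QNetwork) -> Callable[[np.ndarray, np.ndarray], int]:
    """Deterministic (epsilon = 0) policy closure over a trained network."""

    def policy(obs: np.ndarray, mask: np.ndarray) -> int:
        return select_action(net, obs, mask, epsilon=0.0)

    return policy


def save_checkpoint(net: QNetwork, config: DQNConfig, path: str) -> None:
    """Network weights as .npz with a JSON sidecar of config + dimensions."""
    arrays = {f"w{i}": w for i, w in enumerate(net.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(net.biases)})
    np.savez(path, **arrays)
    meta = {
        "in_dim": net.in_dim,
        "out_dim": net.out_dim,
        "hidden": list(net.hidden),
        "config": {
            **{k: getattr(config, k) for k in (
                "learning_rate", "batch_size", "buffer_capacity",
                "target_update_every", "epsilon_start", "epsilon_end",
                "gamma", "train_steps", "warmup_steps", "grad_clip", "seed",
            )},
            "hidden": list(config.hidden),
            "epsilon_decay_steps": config.epsilon_decay_steps,
        },
    }
    sidecar = path + ".json" if not path.endswith(".npz") else path[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(path: str) -> QNetwork:
    if not path.endswith(".npz"):
        path = path + ".npz"
    data = np.load(path)
    sidecar = path[:-4] + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    net = QNetwork(meta["in_dim"], meta["out_dim"], tuple(meta["hidden"]))
    net.weights = [data[f"w{i}"] for i in range(len(net.weights))]
    net.biases = [data[f"b{i}"] for i in range(len(net.biases))]
    return net
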