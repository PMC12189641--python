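"""MDP environment: observation encoding, action masking, the composite
reward, shaping, and the step/reset contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrisched.baselines import fcfs_policy
from mrisched.config import ScenarioConfig
from mrisched.env import (
    MriSchedulingEnv,
    EpisodeFinished,
    RewardParams,
    SchedulingAction,
    legal_action_mask,
    observe,
    reward,
    shaped_beta,
)
from mrisched.twin import BUSY, IllegalActionError


def run_fcfs(env, seed):
    obs, info = env.reset(seed)
    trajectory = []
    while not env.done:
        action = fcfs_policy(env.twin, info["mask"])
        obs, r, done, info = env.step(action)
        trajectory.append((obs.copy(), r))
    return trajectory


class TestObservation:
    def test_empty_system_encodes_to_idle_one_hots(self, tiny_scenario):
        scenario = tiny_scenario.replace(hourly_rates=(0.0,) * 24)
        env = MriSchedulingEnv(scenario, horizon_minutes=10)
        obs, info = env.reset(0)
        assert obs.shape == (1 + 5 * scenario.queue_window + 3 * 3,)
        machine_base = 1 + 5 * scenario.queue_window
        expected = np.zeros_like(obs)
        for j in range(3):
            expected[machine_base + 3 * j] = 1.0  # idle one-hot
        np.testing.assert_array_equal(obs, expected)
        assert list(info["mask"]) == [False] * (env.n_actions - 1) + [True]

    def test_slot_features_for_one_waiting_patient(self, make_twin):
        twin = make_twin([0.0], [30.0], priorities=[2])
        for _ in range(10):
            twin.advance_one_minute()
        obs = observe(twin, queue_window=10, wait_norm=480.0)
        slot0 = obs[1:6]
        np.testing.assert_allclose(slot0, [10 / 480, 0.0, 1.0, 0.0, 1.0])

    def test_queue_longer_than_window_truncates(self, make_twin):
        K = 4
        twin = make_twin([0.0] * (K + 5), [30.0] * (K + 5))
        obs = observe(twin, queue_window=K)
        presence = obs[[1 + 5 * s + 4 for s in range(K)]]
        np.testing.assert_array_equal(presence, np.ones(K))
        assert obs[0] == pytest.approx((K + 5) / K)


class TestActionMask:
    def test_counts_with_partial_idleness(self, make_twin):
        twin = make_twin([0.0] * 3, [30.0] * 3, n_machines=3)
        twin.assign(2, 1)  # one machine busy, two queued remain, two idle
        mask = legal_action_mask(twin, queue_window=10)
        assert mask[-1]  # wait always legal
        assert mask[:-1].sum() == 4  # 2 slots x 2 idle machines
        legal = set(np.flatnonzero(mask[:-1]))
        assert legal == {0 * 3 + 0, 0 * 3 + 2, 1 * 3 + 0, 1 * 3 + 2}

    def test_only_wait_when_no_idle_or_no_queue(self, make_twin):
        busy = make_twin([0.0], [300.0], n_machines=1)
        busy.assign(0, 0)
        assert list(legal_action_mask(busy, 5)) == [False] * 5 + [True]
        empty = make_twin([], [], n_machines=2)
        mask = legal_action_mask(empty, 5)
        assert mask[-1] and mask[:-1].sum() == 0


class TestShapedBeta:
    def test_static_below_and_at_baseline(self):
        params = RewardParams(beta0=1.0, rho=0.5, baseline_queue=10.0)
        assert shaped_beta(0, params) == 1.0
        assert shaped_beta(10, params) == 1.0  # boundary: factor exactly 1

    def test_congestion_scaling_arithmetic(self):
        params = RewardParams(beta0=1.0, rho=0.5, baseline_queue=10.0)
        assert shaped_beta(20, params) == pytest.approx(2.0)

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=100)
    def test_monotone_in_queue_length(self, q1, q2):
        params = RewardParams(beta0=0.7, rho=0.3, baseline_queue=5.0)
        lo, hi = sorted((q1, q2))
        assert shaped_beta(lo, params) <= shaped_beta(hi, params)

    @given(st.integers(0, 500))
    @settings(max_examples=50)
    def test_rho_zero_reduces_to_static_weight(self, q):
        params = RewardParams(beta0=0.7, rho=0.0, baseline_queue=5.0)
        assert shaped_beta(q, params) == 0.7


class TestReward:
    def test_wait_on_empty_queue_costs_only_imbalance(self, make_twin):
        twin = make_twin([0.0], [30.0], n_machines=3)
        twin.assign(0, 0)
        for _ in range(5):
            twin.advance_one_minute()  # one machine accrues busy: imbalance > 0
        params = RewardParams()
        busy = np.array([m.cumulative_busy for m in twin.machines])
        expected = -params.delta * busy.std() / twin.clock
        got = reward(twin, SchedulingAction.wait(), twin, params)
        assert got == pytest.approx(expected)
        assert got < 0

    def test_assign_with_balanced_machines(self, make_twin):
        # two patients queued at clock 0, machines untouched (balanced)
        twin = make_twin([0.0, 0.0], [30.0, 30.0], priorities=[1, 3], n_machines=3)
        params = RewardParams(alpha=1.0, beta0=1.0, delta=0.1)
        twin.assign(0, 0)  # action applied; priority-3 patient left waiting
        expected = 1.0 / 3 - 1.0 * (1.0 / 3) / 60.0
        got = reward(twin, SchedulingAction.assign(0, 0), twin, params)
        assert got == pytest.approx(expected)

    def test_zero_weights_zero_reward(self, make_twin):
        twin = make_twin([0.0, 0.0], [30.0, 30.0], n_machines=2)
        params = RewardParams(alpha=0.0, beta0=0.0, delta=0.0)
        for action in (SchedulingAction.wait(), SchedulingAction.assign(0, 1)):
            assert reward(twin, action, twin, params) == 0.0


class TestStepContract:
    def test_episode_lasts_exactly_horizon_steps(self, tiny_scenario):
        env = MriSchedulingEnv(tiny_scenario, horizon_minutes=120)
        env.reset(3)
        steps = 0
        while not env.done:
            env.step(env.wait_action)
            steps += 1
        assert steps == 120
        with pytest.raises(EpisodeFinished):
            env.step(env.wait_action)

    def test_illegal_action_raises_before_mutation(self, tiny_scenario):
        scenario = tiny_scenario.replace(hourly_rates=(0.0,) * 24)
        env = MriSchedulingEnv(scenario, horizon_minutes=60)
        env.reset(0)
        clock_before = env.twin.clock
        with pytest.raises(IllegalActionError):
            env.step(0)  # empty queue: assign is illegal
        assert env.twin.clock == clock_before

    def test_common_random_numbers_replay_identically(self, tiny_scenario):
        env_a = MriSchedulingEnv(tiny_scenario, horizon_minutes=300)
        env_b = MriSchedulingEnv(tiny_scenario, horizon_minutes=300)
        traj_a = run_fcfs(env_a, seed=5)
        traj_b = run_fcfs(env_b, seed=5)
        for (obs_a, r_a), (obs_b, r_b) in zip(traj_a, traj_b):
            np.testing.assert_array_equal(obs_a, obs_b)
            assert r_a == r_b

    def test_utilization_reward_sum_counts_exam_starts(self, tiny_scenario):
        # alpha=1, beta=delta=0: episode return == (#assignments)/k
        scenario = tiny_scenario.replace(
            reward=RewardParams(alpha=1.0, beta0=0.0, delta=0.0)
        )
        env = MriSchedulingEnv(scenario, horizon_minutes=480)
        obs, info = env.reset(11)
        total = 0.0
        while not env.done:
            action = fcfs_policy(env.twin, info["mask"])
            obs, r, done, info = env.step(action)
            total += r
        assert info["n_assignments"] > 0
        assert total == pytest.approx(info["n_assignments"] / 3)

    def test_masked_actions_are_never_executable(self, tiny_scenario):
        env = MriSchedulingEnv(tiny_scenario, horizon_minutes=200)
        obs, info = env.reset(2)
        rng = np.random.default_rng(0)
        while not env.done:
            mask = info["mask"]
            illegal = np.flatnonzero(~mask)
            if illegal.size:
                with pytest.raises(IllegalActionError):
                    env.step(int(rng.choice(illegal)))
            legal = np.flatnonzero(mask)
            obs, r, done, info = env.step(int(rng.choice(legal)))


class TestConservation:
    @pytest.mark.parametrize("p_fail", [0.0, 0.05])
    def test_patient_accounting_balances_every_minute(self, tiny_scenario, p_fail):
        scenario = tiny_scenario.replace(p_fail_per_hour=p_fail)
        env = MriSchedulingEnv(scenario, horizon_minutes=600)
        obs, info = env.reset(4)
        rng = np.random.default_rng(1)
        while not env.done:
            legal = np.flatnonzero(info["mask"])
            obs, r, done, info = env.step(int(rng.choice(legal)))
            twin = env.twin
            assert (
                len(twin.queue) + twin.n_in_service + len(twin.completed)
                == twin.n_arrived
            )
        twin = env.twin
        assert all(p.wait >= 0 for p in twin.patients if p.wait is not None)
        if p_fail == 0.0:
            assert twin.total_down_minutes() == 0.0


class TestSchedulingAction:
    def test_index_round_trip(self):
        for index in range(31):
            action = SchedulingAction.from_index(index, n_machines=3, queue_window=10)
            assert action.to_index(3, 10) == index
        with pytest.raises(ValueError):
            SchedulingAction.from_index(31, 3, 10)
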