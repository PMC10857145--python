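from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from cfrl.agent import (
    AgentConfig,
    MealEnvironment,
    PRESETS,
    ReplayBuffer,
    Transition,
    make_environment,
    q_update,
    recommend_plan,
    select_action,
    train,
)
from cfrl.cf import build_matrix, fit_svd, predict_acceptance
from cfrl.network import QNetwork
from cfrl.reward import RewardComponents, RewardWeights
from cfrl.synthetic import rating_oracle


class BanditEnv:
    """A one-state multi-armed bandit exposing the environment duck-type
    the training loop expects; rewards are fixed per arm."""

    def __init__(self, arm_rewards, state_dim: int = 1):
        self.arm_rewards = np.asarray(arm_rewards, dtype=float)
        self.candidates = [
            SimpleNamespace(meal_id=f"arm{i}", meal_type="lunch")
            for i in range(len(self.arm_rewards))
        ]
        self._state = np.ones(state_dim)

    @property
    def n_actions(self):
        return len(self.arm_rewards)

    @property
    def state_dim(self):
        return self._state.size

    def reset(self):
        return self._state.copy()

    def action_mask(self, slot=None):
        return np.ones(self.n_actions, dtype=bool)

    def step(self, action):
        r = float(self.arm_rewards[action])
        comps = RewardComponents(ru=r, n=r, p=r, r=r)
        return comps, self._state.copy()


def tabular_q() -> QNetwork:
    """A bias-free linear net on a scalar state: exactly tabular Q-learning."""
    q = QNetwork(1, 1, hidden=(), optimizer="sgd", use_bias=False, seed=0)
    q.W[0][:] = 0.0
    return q


class TestQUpdateArithmetic:
    def test_single_textbook_update(self):
        q = tabular_q()
        s = np.array([1.0])
        minibatch = [Transition(s, 0, 1.0, s)]
        q_update(q, minibatch, alpha=0.01, gamma=0.95)
        # Q was 0 so the TD error is exactly r; Q moves to alpha * r
        assert q.forward(s[None])[0, 0] == pytest.approx(0.01, abs=1e-15)

    def test_gamma_zero_repeated_updates_reach_reward(self):
        q = tabular_q()
        s = np.array([1.0])
        minibatch = [Transition(s, 0, 0.7, s)]
        for _ in range(2000):
            q_update(q, minibatch, alpha=0.05, gamma=0.0)
        assert q.forward(s[None])[0, 0] == pytest.approx(0.7, abs=1e-3)

    def test_zero_td_error_is_fixed_point(self):
        q = QNetwork(3, 4, hidden=(8,), optimizer="sgd", seed=1)
        s = np.ones(3)
        current = q.forward(s[None])[0]
        minibatch = [Transition(s, 2, float(current[2]), s, done=True)]
        before = [w.copy() for w in q.W]
        q_update(q, minibatch, alpha=0.1, gamma=0.0)
        assert all(np.array_equal(a, b) for a, b in zip(before, q.W))

    def test_empty_minibatch_rejected(self):
        with pytest.raises(ValueError):
            q_update(tabular_q(), [], 0.1, 0.9)


class TestSelectAction:
    def test_greedy_when_epsilon_zero(self):
        q = QNetwork(2, 5, hidden=(8,), seed=3)
        rng = np.random.default_rng(0)
        state = np.ones(2)
        expected = int(np.argmax(q.forward(state[None])[0]))
        assert all(select_action(q, state, 0.0, rng) == expected for _ in range(20))

    def test_uniform_when_epsilon_one(self):
        q = QNetwork(2, 4, hidden=(8,), seed=3)
        rng = np.random.default_rng(1)
        counts = np.bincount(
            [select_action(q, np.ones(2), 1.0, rng) for _ in range(10_000)], minlength=4
        )
        expected = 2500
        sigma = np.sqrt(10_000 * 0.25 * 0.75)
        assert np.all(np.abs(counts - expected) < 3 * sigma)

    def test_mask_restricts_both_modes(self):
        q = QNetwork(2, 6, hidden=(8,), seed=3)
        rng = np.random.default_rng(2)
        mask = np.array([False, True, False, True, False, False])
        for eps in (0.0, 1.0):
            for _ in range(50):
                assert select_action(q, np.ones(2), eps, rng, mask) in (1, 3)

    def test_seeded_sequence_reproducible(self):
        q = QNetwork(2, 5, hidden=(8,), seed=3)
        seq1 = [select_action(q, np.ones(2), 0.5, np.random.default_rng(7)) for _ in range(1)]
        a = [select_action(q, np.ones(2), 0.5, np.random.default_rng(7)) for _ in range(10)]
        b = [select_action(q, np.ones(2), 0.5, np.random.default_rng(7)) for _ in range(10)]
        assert a == b


class TestReplayBuffer:
    def test_fifo_eviction_at_capacity(self):
        buf = ReplayBuffer(capacity=3)
        s = np.zeros(1)
        for i in range(5):
            buf.push(Transition(s, i, 0.0, s))
        assert len(buf) == 3
        assert sorted(t.action for t in buf._store) == [2, 3, 4]

    def test_minibatch_sampled_without_replacement(self):
        buf = ReplayBuffer(capacity=10)
        s = np.zeros(1)
        for i in range(10):
            buf.push(Transition(s, i, 0.0, s))
        batch = buf.sample(10, np.random.default_rng(0))
        assert sorted(t.action for t in batch) == list(range(10))


@pytest.fixture(scope="module")
def fitted(small_world_module):
    world, interactions = small_world_module
    R = build_matrix(
        interactions, [u.user_id for u in world.users], [m.meal_id for m in world.meals]
    )
    return world, interactions, fit_svd(R, k=4, epochs=40, seed=7)


@pytest.fixture(scope="module")
def small_world_module():
    from cfrl.synthetic import generate_world

    return generate_world(n_users=30, n_meals=18, density=0.4, seed=7)


def env_for(world, factors, user_idx=0, weights=None, oracle_seed=11):
    return MealEnvironment(
        world.users[user_idx],
        world.meals,
        factors,
        weights or RewardWeights(),
        rating_oracle(world, seed=oracle_seed),
    )


class TestMealEnvironment:
    def test_reset_returns_fitted_user_state(self, fitted):
        world, _, factors = fitted
        env = env_for(world, factors)
        s1, s2 = env.reset(), env.reset()
        assert np.array_equal(s1, s2)
        assert np.array_equal(s1, factors.user_state(world.users[0].user_id))

    def test_step_reward_bounded_and_conserved(self, fitted):
        world, _, factors = fitted
        env = env_for(world, factors)
        env.reset()
        w = env.reward_weights
        for action in np.flatnonzero(env.action_mask())[:3]:
            comps, _ = env.step(int(action))
            env.reset()
            assert 0.0 <= comps.r <= 1.0
            assert comps.r == pytest.approx(w.w_r * comps.ru + w.w_n * comps.n + w.w_p * comps.p)

    def test_slots_cycle_breakfast_lunch_dinner(self, fitted):
        world, _, factors = fitted
        env = env_for(world, factors)
        env.reset()
        seen = []
        for _ in range(3):
            slot = env.current_slot
            seen.append(slot)
            action = int(np.flatnonzero(env.action_mask())[0])
            assert env.candidates[action].meal_type == slot
            env.step(action)
        assert seen == ["breakfast", "lunch", "dinner"]

    def test_high_rating_raises_predicted_acceptance(self, fitted):
        world, _, factors = fitted
        env = env_for(world, factors)
        env.reset()
        user = env.profile.user_id
        meal = env.candidates[0]

        def forced_five(u, m):
            return 5

        env.rating_oracle = forced_five
        before, _ = predict_acceptance(env.factors, user, meal.meal_id)
        for _ in range(5):
            env.step(0)
            env._step = 0  # stay on the same slot for a repeated rating
        after, _ = predict_acceptance(env.factors, user, meal.meal_id)
        if before < 5.0:
            assert after > before

    def test_empty_candidate_set_rejected(self, fitted):
        world, _, factors = fitted
        with pytest.raises(ValueError, match="empty"):
            MealEnvironment(
                world.users[0], [], factors, RewardWeights(), rating_oracle(world, 1)
            )

    def test_make_environment_applies_constraints(self, fitted):
        world, _, factors = fitted
        profile = world.users[0]
        profile.hard_constraints = ["low_sodium"]
        env = make_environment(
            profile, world.meals, factors, RewardWeights(), rating_oracle(world, 1)
        )
        assert all(m.nutrients.sodium_mg <= 600 for m in env.candidates)
        profile.hard_constraints = []


class TestTrainingLoop:
    def test_zero_episodes_returns_untrained_network(self, fitted):
        world, _, factors = fitted
        env = env_for(world, factors)
        config = AgentConfig(episodes=0, seed=0)
        q, results = train(config, [env])
        assert results == []
        assert isinstance(q, QNetwork)

    def test_training_is_bitwise_reproducible(self, fitted):
        world, _, factors = fitted
        def run():
            env = env_for(world, factors, oracle_seed=5)
            q, results = train(AgentConfig(episodes=15, seed=3), [env])
            return q, results
        q1, r1 = run()
        q2, r2 = run()
        assert all(np.array_equal(a, b) for a, b in zip(q1.W, q2.W))
        assert [r.rewards for r in r1] == [r.rewards for r in r2]

    def test_bandit_learning_curve_improves(self):
        env = BanditEnv([0.1, 0.2, 0.3, 0.4, 0.9])
        config = AgentConfig(episodes=200, steps_per_episode=3, seed=0, lr=0.01)
        q, results = train(config, [env])
        assert int(np.argmax(q.forward(np.ones((1, 1)))[0])) == 4
        rewards = [r.mean_reward for r in results]
        assert np.mean(rewards[-50:]) > np.mean(rewards[:50])

    def test_shipped_preset_hyperparameters(self):
        assert PRESETS["methods"].lr == 0.01 and PRESETS["methods"].gamma == 0.95
        assert PRESETS["experiments"].lr == 25e-4 and PRESETS["experiments"].gamma == 0.99


class TestRecommendPlan:
    def test_single_meal_per_type_catalogue(self, fitted):
        world, _, factors = fitted
        singles = [
            next(m for m in world.meals if m.meal_type == t)
            for t in ("breakfast", "lunch", "dinner")
        ]
        env = MealEnvironment(
            world.users[0], singles, factors, RewardWeights(), rating_oracle(world, 1)
        )
        q = QNetwork(env.state_dim, env.n_actions, hidden=(8,), seed=0)
        plan = recommend_plan(q, env)
        assert [p.meal.meal_id for p in plan] == [m.meal_id for m in singles]

    def test_reported_scores_in_documented_ranges(self, fitted):
        world, _, factors = fitted
        env = env_for(world, factors)
        q = QNetwork(env.state_dim, env.n_actions, hidden=(8,), seed=0)
        for item in recommend_plan(q, env):
            assert 0.0 <= item.preference <= 1.0
            assert 0.0 <= item.pv <= 1.0
            assert 1.0 <= item.predicted_acceptance <= 5.0

    def test_missing_slot_named_in_error(self, fitted):
        world, _, factors = fitted
        lunches = [m for m in world.meals if m.meal_type == "lunch"]
        env = MealEnvironment(
            world.users[0], lunches, factors, RewardWeights(), rating_oracle(world, 1)
        )
        q = QNetwork(env.state_dim, env.n_actions, hidden=(8,), seed=0)
        with pytest.raises(ValueError, match="breakfast"):
            recommend_plan(q, env)

    def test_greedy_plan_beats_median_random_plan(self, fitted):
        world, _, factors = fitted
        env = env_for(world, factors, weights=RewardWeights(1.0, 0.0, 0.0))
        config = AgentConfig(episodes=150, seed=1)
        q, _ = train(config, [env])
        plan = recommend_plan(q, env)
        user = env.profile.user_id
        greedy_utility = np.mean([world.utility(user, p.meal.meal_id) for p in plan])
        rng = np.random.default_rng(0)
        random_utils = []
        for _ in range(100):
            picks = [
                env.candidates[rng.choice(slots)].meal_id
                for slots in env._type_slots.values()
            ]
            random_utils.append(np.mean([world.utility(user, m) for m in picks]))
        assert greedy_utility >= np.median(random_utils)
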