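"""The interactive recommendation MDP and the DQN agent.

One environment wraps one user: the state is the user's latent-factor row
from the collaborative-filtering model; an action is the index of a meal in
the user's (constraint-filtered) candidate catalogue.  A step recommends the
meal, obtains a rating from the rating oracle (a simulated or real user),
composes the scalar reward from the normalized rating, the meal's fuzzy
nutrition score, and its TOPSIS preference score, and advances the state by
one online update of the user's latent row.

Training is standard deep Q-learning with uniform experience replay and an
epsilon-greedy policy whose exploration rate decays multiplicatively per
episode.  Two hyperparameter presets are shipped:

* ``"methods"``      — lr 0.01,   discount 0.95
* ``"experiments"``  — lr 0.0025, discount 0.99  (default)
"""
from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cf import LatentFactors, predict_user_vector, update_user_latent
from .datatypes import MEAL_TYPES, Meal, UserProfile
from .mcdm import CriterionSpec, criteria_from_profile, topsis_score
from .network import QNetwork
from .nutrition import MembershipSpec, resolve_membership_specs, score_meal_nutrition
from .reward import RewardComponents, RewardWeights, compose_reward, normalize_rating

logger = logging.getLogger(__name__)

RatingOracle = Callable[[str, str], int]


@dataclass(frozen=True)
class AgentConfig:
    """DQN hyperparameters; see module docstring for the presets."""

    lr: float = 25e-4
    gamma: float = 0.99
    epsilon: float = 1.0
    epsilon_min: float = 0.05
    epsilon_decay: float = 0.995
    episodes: int = 300
    steps_per_episode: int = 3
    replay_capacity: int = 10_000
    minibatch: int = 32
    hidden: tuple[int, ...] = (128, 64, 32)
    seed: int = 0
    target_sync: int | None = None  # None = bootstrap from the online network

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.replay_capacity < self.minibatch:
            raise ValueError("replay capacity must be >= minibatch size")


PRESETS: dict[str, AgentConfig] = {
    "methods": AgentConfig(lr=0.01, gamma=0.95),
    "experiments": AgentConfig(lr=25e-4, gamma=0.99),
}


class Transition(NamedTuple):
    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    done: bool = False  # terminal step: no bootstrap beyond it
    next_mask: np.ndarray | None = None  # valid actions in the next state


class ReplayBuffer:
    """Bounded FIFO memory with uniform minibatch sampling (no replacement
    within a minibatch)."""

    def __init__(self, capacity: int = 10_000) -> None:
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._store: deque[Transition] = deque(maxlen=capacity)

    def push(self, transition: Transition) -> None:
        self._store.append(transition)

    def __len__(self) -> int:
        return len(self._store)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        if batch_size > len(self._store):
            raise ValueError("not enough transitions to sample")
        idx = rng.choice(len(self._store), size=batch_size, replace=False)
        return [self._store[i] for i in idx]


class MealEnvironment:
    """One user's interactive recommendation loop.

    ``reset()`` restores the state to the fitted latent row; ``step(a)``
    recommends candidate ``a``, collects a rating, and returns
    ``(reward_components, next_state)``.  The environment works on a private
    copy of the factors, so episodes never mutate the fitted model.
    """

    def __init__(
        self,
        profile: UserProfile,
        candidates: Sequence[Meal],
        factors: LatentFactors,
        reward_weights: RewardWeights,
        rating_oracle: RatingOracle,
        membership_specs: dict[str, MembershipSpec] | None = None,
        criteria: Sequence[CriterionSpec] | None = None,
        update_eta: float = 0.05,
        update_reg: float = 0.0,
    ) -> None:
        if not candidates:
            raise ValueError("candidate set is empty after constraint filtering")
        if profile.user_id not in factors.user_index:
            raise KeyError(f"user {profile.user_id!r} unknown to the CF model")
        self.profile = profile
        self.candidates = list(candidates)
        self.reward_weights = reward_weights
        self.rating_oracle = rating_oracle
        self.update_eta = update_eta
        self.update_reg = update_reg
        self._fitted = factors
        self.factors = factors.copy()
        specs = resolve_membership_specs(profile, membership_specs)
        self.pv = np.array(
            [score_meal_nutrition(m, specs=specs).pv for m in self.candidates]
        )
        self.cost = np.array(
            [float(m.attributes.get("cost", 1.0)) for m in self.candidates]
        )
        self.prep = np.array(
            [float(m.attributes.get("prep_minutes", 30.0)) for m in self.candidates]
        )
        self.criteria = (
            list(criteria)
            if criteria is not None
            else criteria_from_profile(profile, ["nutrition", "taste", "cost", "convenience"])
        )
        self._meal_rows = np.array(
            [factors.meal_index.get(m.meal_id, -1) for m in self.candidates]
        )
        if np.any(self._meal_rows < 0):
            raise KeyError("candidate meal unknown to the CF model")
        self._type_slots = {
            t: [i for i, m in enumerate(self.candidates) if m.meal_type == t]
            for t in MEAL_TYPES
        }
        # an episode walks the day's slots in order; slots without any
        # candidate are skipped (e.g. a breakfast-only catalogue)
        self._schedule = [t for t in MEAL_TYPES if self._type_slots[t]]
        self._step = 0

    @property
    def n_actions(self) -> int:
        return len(self.candidates)

    @property
    def state_dim(self) -> int:
        return self._fitted.k

    def reset(self) -> np.ndarray:
        self.factors = self._fitted.copy()
        self._step = 0
        return self.factors.user_state(self.profile.user_id)

    @property
    def current_slot(self) -> str:
        """The meal type the next action fills (slots cycle per step)."""
        return self._schedule[self._step % len(self._schedule)]

    def action_mask(self, slot: str | None = None) -> np.ndarray:
        """Boolean mask of candidates valid for the given (or current) slot."""
        mask = np.zeros(self.n_actions, dtype=bool)
        mask[self._type_slots[slot or self.current_slot]] = True
        return mask

    def _predicted_acceptance(self) -> np.ndarray:
        """Normalized predicted acceptance for every candidate (current state)."""
        preds = predict_user_vector(self.factors, self.profile.user_id)
        return (preds[self._meal_rows] - 1.0) / 4.0

    def preference_scores(self) -> np.ndarray:
        """TOPSIS preference of each candidate under the current state."""
        if len(self.candidates) == 1:
            return np.array([1.0])
        A = np.column_stack([self.pv, self._predicted_acceptance(), self.cost, self.prep])
        return topsis_score(A, self.criteria).scores

    def step(self, action: int) -> tuple[RewardComponents, np.ndarray]:
        if not 0 <= action < self.n_actions:
            raise IndexError(f"action {action} outside [0, {self.n_actions})")
        meal = self.candidates[action]
        self._step += 1
        rating = int(self.rating_oracle(self.profile.user_id, meal.meal_id))
        components = compose_reward(
            ru=normalize_rating(rating),
            n=float(self.pv[action]),
            p=float(self.preference_scores()[action]),
            weights=self.reward_weights,
        )
        update_user_latent(
            self.factors, self.profile.user_id, meal.meal_id, rating,
            eta=self.update_eta, reg=self.update_reg,
        )
        return components, self.factors.user_state(self.profile.user_id)


def make_environment(
    profile: UserProfile,
    catalogue: Sequence[Meal],
    factors: LatentFactors,
    reward_weights: RewardWeights,
    rating_oracle: RatingOracle,
    apply_constraints: bool = True,
    **kwargs,
) -> MealEnvironment:
    """Convenience constructor that applies the user's hard constraints."""
    from .io import apply_hard_constraints

    candidates = (
        apply_hard_constraints(catalogue, profile) if apply_constraints else list(catalogue)
    )
    return MealEnvironment(
        profile, candidates, factors, reward_weights, rating_oracle, **kwargs
    )


def select_action(
    q: QNetwork,
    state: np.ndarray,
    epsilon: float,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> int:
    """Epsilon-greedy action; greedy ties resolve to the lowest index.

    ``mask`` restricts both exploration and the greedy argmax to the valid
    actions (e.g. the meals of the slot being filled).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if mask is None:
        mask = np.ones(q.n_actions, dtype=bool)
    valid = np.flatnonzero(mask)
    if valid.size == 0:
        raise ValueError("action mask excludes every action")
    if rng.random() < epsilon:
        return int(valid[rng.integers(valid.size)])
    qvals = q.forward(state[None, :])[0]
    return int(valid[np.argmax(qvals[valid])])


def q_update(
    q: QNetwork,
    minibatch: Sequence[Transition],
    alpha: float,
    gamma: float,
    target_net: QNetwork | None = None,
) -> float:
    """One gradient step on the squared TD error of a minibatch.

    Targets are ``r + gamma * max_a Q(s', a)`` bootstrapped from the online
    network unless a frozen target network is supplied.  Returns the mean
    squared TD error.
    """
    if not minibatch:
        raise ValueError("minibatch must be non-empty")
    bootstrap = target_net if target_net is not None else q
    states = np.stack([t.state for t in minibatch])
    next_states = np.stack([t.next_state for t in minibatch])
    rewards = np.array([t.reward for t in minibatch])
    actions = np.array([t.action for t in minibatch])
    live = 1.0 - np.array([t.done for t in minibatch], dtype=float)
    next_q = bootstrap.forward(next_states)
    best_next = np.empty(len(minibatch))
    for i, t in enumerate(minibatch):
        best_next[i] = (
            next_q[i].max() if t.next_mask is None else next_q[i][t.next_mask].max()
        )
    targets = rewards + gamma * live * best_next
    return q.td_step(states, actions, targets, lr=alpha)


@dataclass
class EpisodeResult:
    episode: int
    meal_ids: list[str]
    rewards: list[float]
    ru: list[float]
    n: list[float]
    p: list[float]
    epsilon: float

    @property
    def mean_reward(self) -> float:
        return float(np.mean(self.rewards))


def results_frame(results: Sequence[EpisodeResult]) -> pd.DataFrame:
    """Flatten per-episode results into one row per step."""
    rows = []
    for res in results:
        for t in range(len(res.meal_ids)):
            rows.append(
                {
                    "episode": res.episode,
                    "step": t,
                    "meal_id": res.meal_ids[t],
                    "reward": res.rewards[t],
                    "ru": res.ru[t],
                    "n": res.n[t],
                    "p": res.p[t],
                    "epsilon": res.epsilon,
                }
            )
    return pd.DataFrame(
        rows, columns=["episode", "step", "meal_id", "reward", "ru", "n", "p", "epsilon"]
    )


def train(
    config: AgentConfig,
    environments: Sequence[MealEnvironment],
    q: QNetwork | None = None,
) -> tuple[QNetwork, list[EpisodeResult]]:
    """Run the full training loop: per episode pick a user environment,
    roll out ``steps_per_episode`` epsilon-greedy steps, store transitions,
    and update the Q-network on replayed minibatches."""
    if not environments:
        raise ValueError("need at least one environment")
    n_actions = environments[0].n_actions
    state_dim = environments[0].state_dim
    for env in environments:
        if env.n_actions != n_actions or env.state_dim != state_dim:
            raise ValueError("all environments must share one action/state space")
    rng = np.random.default_rng(config.seed)
    if q is None:
        q = QNetwork(
            state_dim, n_actions, hidden=config.hidden, seed=config.seed, lr=config.lr
        )
    target = q.clone() if config.target_sync else None
    buffer = ReplayBuffer(config.replay_capacity)
    epsilon = config.epsilon
    results: list[EpisodeResult] = []
    updates = 0
    for episode in range(config.episodes):
        env = environments[int(rng.integers(len(environments)))]
        state = env.reset()
        meal_ids, rewards, rus, ns, ps = [], [], [], [], []
        for t in range(config.steps_per_episode):
            action = select_action(q, state, epsilon, rng, env.action_mask())
            components, next_state = env.step(action)
            done = t == config.steps_per_episode - 1
            next_mask = None if done else env.action_mask()
            buffer.push(
                Transition(state, action, components.r, next_state, done, next_mask)
            )
            meal_ids.append(env.candidates[action].meal_id)
            rewards.append(components.r)
            rus.append(components.ru)
            ns.append(components.n)
            ps.append(components.p)
            state = next_state
            if len(buffer) >= config.minibatch:
                loss = q_update(
                    q, buffer.sample(config.minibatch, rng), config.lr, config.gamma, target
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite TD loss at episode {episode}; aborting training"
                    )
                updates += 1
                if target is not None and updates % config.target_sync == 0:
                    target.copy_weights_from(q)
        results.append(
            EpisodeResult(episode, meal_ids, rewards, rus, ns, ps, epsilon)
        )
        epsilon = max(config.epsilon_min, epsilon * config.epsilon_decay)
    return q, results


@dataclass
class PlanItem:
    meal_type: str
    meal: Meal
    preference: float
    pv: float
    predicted_acceptance: float  # on the 1-5 rating scale


def recommend_plan(
    q: QNetwork,
    environment: MealEnvironment,
    meal_types: Sequence[str] = MEAL_TYPES,
) -> list[PlanItem]:
    """Greedy (epsilon = 0) recommendation of one meal per requested slot,
    with the scores a report would print for each pick."""
    state = environment.reset()
    qvals = q.forward(state[None, :])[0]
    prefs = environment.preference_scores()
    accept = environment._predicted_acceptance() * 4.0 + 1.0
    plan: list[PlanItem] = []
    for meal_type in meal_types:
        slots = environment._type_slots.get(meal_type, [])
        if not slots:
            raise ValueError(f"no candidate meals for slot {meal_type!r}")
        best = slots[int(np.argmax(qvals[slots]))]
        plan.append(
            PlanItem(
                meal_type=meal_type,
                meal=environment.candidates[best],
                preference=float(prefs[best]),
                pv=float(environment.pv[best]),
                predicted_acceptance=float(accept[best]),
            )
        )
    return plan
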