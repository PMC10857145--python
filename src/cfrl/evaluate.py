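"""Method comparison harness: metrics, baselines, and grid search.

Every method produces one meal plan (breakfast/lunch/dinner) per evaluation
user; plans are scored by three metrics, averaged over meals, users, and
repeated runs:

* **avg PV** in [0, 1] — fuzzy nutritional adequacy of the recommended meals;
* **avg preference** in [0, 1] — TOPSIS closeness of each recommended meal
  within the user's candidate set;
* **avg acceptance** in [1, 5] — the rating the (simulated) user actually
  gives the recommended meal.

Methods:

* ``cfrl`` — the full loop: DQN trained on the composite reward
  (rating + nutrition + preference) over CF states;
* ``cf`` — pick the meal with the highest CF-predicted rating per slot;
* ``nutrition`` — the same DQN loop with the rating weight zeroed
  (reward = nutrition + preference only);
* ``nutrition-pref`` — no learning: rank candidates by the multi-criteria
  preference score (PV is an explicit criterion) and take the top per slot.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .agent import AgentConfig, MealEnvironment, recommend_plan, train
from .cf import LatentFactors, build_matrix, fit_svd, predict_user_vector
from .datatypes import MEAL_TYPES, Interaction
from .io import train_test_split
from .reward import RewardWeights
from .synthetic import SyntheticWorld, rating_oracle

logger = logging.getLogger(__name__)

METHOD_NAMES = ("cfrl", "cf", "nutrition", "nutrition-pref")

DEFAULT_WEIGHTS = RewardWeights(w_r=0.3, w_n=0.4, w_p=0.3)
NUTRITION_ONLY_WEIGHTS = RewardWeights(w_r=0.0, w_n=0.4, w_p=0.3)


@dataclass
class MethodResult:
    method: str
    avg_pv: float
    avg_pref: float
    avg_accept: float
    n_runs: int
    per_run: pd.DataFrame  # columns: run, avg_pv, avg_pref, avg_accept


def _run_seed(master_seed: int, run: int) -> int:
    return int((master_seed * 100_003 + 7_919 * run + 13) % (2**31))


def _slot_indices(env: MealEnvironment) -> dict[str, list[int]]:
    return {t: env._type_slots[t] for t in MEAL_TYPES}


def _score_plan(
    env: MealEnvironment,
    picks: Mapping[str, int],
    oracle: Callable[[str, str], int],
) -> tuple[list[float], list[float], list[float]]:
    """PV / preference / oracle-rating triples for one user's plan."""
    prefs = env.preference_scores()
    pvs, ps, accepts = [], [], []
    for meal_type in MEAL_TYPES:
        idx = picks[meal_type]
        meal = env.candidates[idx]
        pvs.append(float(env.pv[idx]))
        ps.append(float(prefs[idx]))
        accepts.append(float(oracle(env.profile.user_id, meal.meal_id)))
    return pvs, ps, accepts


def _greedy_by(env: MealEnvironment, values: np.ndarray) -> dict[str, int]:
    return {
        t: slots[int(np.argmax(values[slots]))]
        for t, slots in _slot_indices(env).items()
    }


def _plans_for_run(
    method: str,
    world: SyntheticWorld,
    factors: LatentFactors,
    run_seed: int,
    n_train_envs: int,
    n_eval_users: int,
    agent_config: AgentConfig | None,
) -> tuple[list[MealEnvironment], list[dict[str, int]]]:
    """Train/apply one method and return per-user (environment, picks)."""
    rng = np.random.default_rng(run_seed)
    oracle = rating_oracle(world, seed=run_seed)
    candidates = world.meals

    def user_env(profile, weights=DEFAULT_WEIGHTS):
        return MealEnvironment(profile, candidates, factors, weights, oracle)

    eval_idx = rng.choice(len(world.users), size=min(n_eval_users, len(world.users)), replace=False)
    eval_users = [world.users[i] for i in sorted(eval_idx)]

    if method in ("cfrl", "nutrition"):
        weights = DEFAULT_WEIGHTS if method == "cfrl" else NUTRITION_ONLY_WEIGHTS
        train_idx = rng.choice(
            len(world.users), size=min(n_train_envs, len(world.users)), replace=False
        )
        envs = [
            MealEnvironment(world.users[i], candidates, factors, weights, oracle)
            for i in sorted(train_idx)
        ]
        config = agent_config or AgentConfig()
        config = AgentConfig(
            **{**config.__dict__, "seed": run_seed}
        )
        q, _ = train(config, envs)
        envs_eval = [user_env(u, weights) for u in eval_users]
        picks = []
        for env in envs_eval:
            plan = recommend_plan(q, env)
            by_id = {m.meal_id: i for i, m in enumerate(env.candidates)}
            picks.append({item.meal_type: by_id[item.meal.meal_id] for item in plan})
        return envs_eval, picks

    envs_eval = [user_env(u) for u in eval_users]
    picks = []
    for env in envs_eval:
        if method == "cf":
            predicted = predict_user_vector(factors, env.profile.user_id)[env._meal_rows]
            picks.append(_greedy_by(env, predicted))
        elif method == "nutrition-pref":
            picks.append(_greedy_by(env, env.preference_scores()))
        else:
            raise ValueError(f"unknown method {method!r}; known: {METHOD_NAMES}")
    return envs_eval, picks


def evaluate_method(
    method: str,
    world: SyntheticWorld,
    interactions: Sequence[Interaction],
    runs: int = 10,
    seed: int = 0,
    n_train_envs: int = 25,
    n_eval_users: int = 20,
    agent_config: AgentConfig | None = None,
    factors: LatentFactors | None = None,
    cf_k: int = 8,
    cf_epochs: int = 30,
) -> MethodResult:
    """Score one method over repeated seeded runs on a synthetic world.

    The CF model is fitted once on the 70% training split of the rating
    history and shared by all runs; per-run seeds derive from the master
    seed and drive agent initialization, user sampling, and rating noise.
    """
    if method not in METHOD_NAMES:
        raise ValueError(f"unknown method {method!r}; known: {METHOD_NAMES}")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if factors is None:
        train_set, _ = train_test_split(interactions, 0.7, seed=seed)
        R = build_matrix(
            train_set,
            users=[u.user_id for u in world.users],
            meals=[m.meal_id for m in world.meals],
        )
        factors = fit_svd(R, k=cf_k, epochs=cf_epochs, lr=0.01, reg=0.05, seed=seed)
    rows = []
    for run in range(runs):
        envs, picks = _plans_for_run(
            method, world, factors, _run_seed(seed, run),
            n_train_envs, n_eval_users, agent_config,
        )
        oracle = rating_oracle(world, seed=_run_seed(seed, run) + 1)
        pvs, prefs, accepts = [], [], []
        for env, pick in zip(envs, picks):
            pv, p, a = _score_plan(env, pick, oracle)
            pvs += pv
            prefs += p
            accepts += a
        rows.append(
            {
                "run": run,
                "avg_pv": float(np.mean(pvs)),
                "avg_pref": float(np.mean(prefs)),
                "avg_accept": float(np.mean(accepts)),
            }
        )
    per_run = pd.DataFrame(rows)
    return MethodResult(
        method=method,
        avg_pv=float(per_run["avg_pv"].mean()),
        avg_pref=float(per_run["avg_pref"].mean()),
        avg_accept=float(per_run["avg_accept"].mean()),
        n_runs=runs,
        per_run=per_run,
    )


def run_comparison(
    world: SyntheticWorld,
    interactions: Sequence[Interaction],
    methods: Sequence[str] = METHOD_NAMES,
    runs: int = 10,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Compare methods under one shared CF fit and master seed.

    Returns the summary table (one row per method) and one-way ANOVA
    p-values across methods for each metric (descriptive only).
    """
    train_set, _ = train_test_split(interactions, 0.7, seed=seed)
    R = build_matrix(
        train_set,
        users=[u.user_id for u in world.users],
        meals=[m.meal_id for m in world.meals],
    )
    factors = fit_svd(
        R, k=kwargs.pop("cf_k", 8), epochs=kwargs.pop("cf_epochs", 30),
        lr=0.01, reg=0.05, seed=seed,
    )
    results = [
        evaluate_method(
            m, world, interactions, runs=runs, seed=seed, factors=factors, **kwargs
        )
        for m in methods
    ]
    table = pd.DataFrame(
        [
            {
                "method": r.method,
                "avg_pv": r.avg_pv,
                "avg_pref": r.avg_pref,
                "avg_accept": r.avg_accept,
                "n_runs": r.n_runs,
            }
            for r in results
        ]
    )
    anova: dict[str, float] = {}
    if len(results) >= 2 and runs >= 2:
        for metric in ("avg_pv", "avg_pref", "avg_accept"):
            groups = [r.per_run[metric].to_numpy() for r in results]
            anova[metric] = float(scipy.stats.f_oneway(*groups).pvalue)
    return table, anova


def grid_search(
    grid: Mapping[str, Sequence],
    objective: Callable[[dict, int], float],
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over the cartesian parameter grid.

    Each cell is evaluated with the same fixed seed; the best cell is the
    argmax of the objective with ties resolved to the earliest cell in grid
    order.  Returns the winning parameters and the full results table.
    """
    names = list(grid.keys())
    combos = list(itertools.product(*(grid[n] for n in names)))
    if not combos:
        raise ValueError("parameter grid is empty")
    rows = []
    best_params, best_value = None, -np.inf
    for combo in combos:
        params = dict(zip(names, combo))
        value = float(objective(params, seed))
        rows.append({**params, "objective": value})
        if value > best_value:
            best_params, best_value = params, value
    return best_params, pd.DataFrame(rows)
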