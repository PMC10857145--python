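"""Synthetic users, meals, and ratings for end-to-end testing without data
downloads.

The generator emulates the statistical shape the pipeline assumes:

* a latent-factor preference structure — each user and meal gets a
  ``k_true``-dimensional Gaussian vector, plus a per-meal popularity offset
  and a per-user generosity offset (rating data are strongly item-biased in
  practice), squashed through a logistic into a true utility
  ``u*(user, meal)`` in [0, 1];
* per-meal-type log-normal nutrient vectors spanning realistic magnitudes
  (e.g. calories roughly 100-800 kcal per meal, sodium tens to >1000 mg);
* sparse explicit ratings ``clip(round(1 + 4 u* + N(0, sigma)), 1, 5)``
  observed at a configurable density.

Everything is driven by one seed; the rating oracle draws from its own
stream so that repeated queries are reproducible in sequence.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .datatypes import MEAL_TYPES, Interaction, Meal, NutrientProfile, UserProfile

logger = logging.getLogger(__name__)

#: Log-normal (median, sigma-of-log) per nutrient and meal type.
NUTRIENT_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "breakfast": {
        "calories": (300.0, 0.45), "carbohydrate_g": (35.0, 0.5),
        "sodium_mg": (300.0, 0.8), "sugar_g": (8.0, 0.8), "fiber_g": (3.0, 0.6),
        "protein_g": (10.0, 0.6), "fat_g": (12.0, 0.5),
    },
    "lunch": {
        "calories": (450.0, 0.4), "carbohydrate_g": (45.0, 0.5),
        "sodium_mg": (600.0, 0.7), "sugar_g": (8.0, 0.8), "fiber_g": (4.0, 0.6),
        "protein_g": (25.0, 0.5), "fat_g": (18.0, 0.5),
    },
    "dinner": {
        "calories": (550.0, 0.4), "carbohydrate_g": (40.0, 0.5),
        "sodium_mg": (650.0, 0.7), "sugar_g": (6.0, 0.8), "fiber_g": (4.0, 0.6),
        "protein_g": (30.0, 0.5), "fat_g": (20.0, 0.5),
    },
}

CUISINES = ("american", "italian", "mexican", "asian", "mediterranean")

MEAL_BIAS_SD = 1.0  # popularity spread across meals (logit scale)
USER_BIAS_SD = 0.3  # generosity spread across users (logit scale)
LATENT_SCALE = 0.5  # personal-taste spread on top of popularity
LOGIT_SCALE = 1.2


@dataclass
class SyntheticWorld:
    """Ground truth behind a simulated population: latent vectors, true
    utilities, and the rating-noise level."""

    meals: list[Meal]
    users: list[UserProfile]
    user_latent: np.ndarray  # n_users x k_true
    meal_latent: np.ndarray  # n_meals x k_true
    user_bias: np.ndarray
    meal_bias: np.ndarray
    noise_sd: float
    seed: int
    user_index: dict[str, int] = field(init=False)
    meal_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.user_index = {u.user_id: i for i, u in enumerate(self.users)}
        self.meal_index = {m.meal_id: j for j, m in enumerate(self.meals)}
        self._oracle_rng = np.random.default_rng([self.seed, 0xFEED])

    def utility_matrix(self) -> np.ndarray:
        """True utilities u* for every (user, meal) pair, in [0, 1]."""
        k = self.user_latent.shape[1]
        z = (
            LATENT_SCALE * self.user_latent @ self.meal_latent.T / np.sqrt(k)
            + self.meal_bias[None, :]
            + self.user_bias[:, None]
        )
        return 1.0 / (1.0 + np.exp(-z / LOGIT_SCALE))

    def utility(self, user_id: str, meal_id: str) -> float:
        i, j = self.user_index[user_id], self.meal_index[meal_id]
        k = self.user_latent.shape[1]
        z = (
            LATENT_SCALE * float(self.user_latent[i] @ self.meal_latent[j]) / np.sqrt(k)
            + self.meal_bias[j]
            + self.user_bias[i]
        )
        return float(1.0 / (1.0 + np.exp(-z / LOGIT_SCALE)))

    def draw_rating(self, user_id: str, meal_id: str, rng: np.random.Generator) -> int:
        u = self.utility(user_id, meal_id)
        raw = 1.0 + 4.0 * u + rng.normal(0.0, self.noise_sd)
        return int(np.clip(np.round(raw), 1, 5))


def _draw_nutrients(meal_type: str, rng: np.random.Generator) -> NutrientProfile:
    params = NUTRIENT_DISTRIBUTIONS[meal_type]
    values = {
        name: float(median * np.exp(rng.normal(0.0, sigma)))
        for name, (median, sigma) in params.items()
    }
    # keep the label arithmetically sane: sugar and fiber cannot exceed carbs
    values["sugar_g"] = min(values["sugar_g"], values["carbohydrate_g"])
    values["fiber_g"] = min(values["fiber_g"], values["carbohydrate_g"])
    return NutrientProfile(**values)


def generate_world(
    n_users: int = 200,
    n_meals: int = 100,
    k_true: int = 2,
    noise_sd: float = 0.3,
    density: float = 0.1,
    seed: int = 0,
    constraint_fraction: float = 0.0,
) -> tuple[SyntheticWorld, list[Interaction]]:
    """Generate a seeded population, catalogue, and sparse rating history.

    ``constraint_fraction`` optionally gives that share of users one hard
    dietary constraint (off by default so every user shares one candidate
    catalogue, hence one agent action space).
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    meals: list[Meal] = []
    for j in range(n_meals):
        meal_type = MEAL_TYPES[j % len(MEAL_TYPES)]
        meals.append(
            Meal(
                meal_id=f"m{j:04d}",
                name=f"{meal_type} dish {j}",
                meal_type=meal_type,
                nutrients=_draw_nutrients(meal_type, rng),
                attributes={
                    "cost": round(float(8.0 * np.exp(rng.normal(0.0, 0.5))), 2),
                    "prep_minutes": round(float(25.0 * np.exp(rng.normal(0.0, 0.6))), 1),
                    "contains_gluten": bool(rng.random() < 0.4),
                    "vegetarian": bool(rng.random() < 0.3),
                    "cuisine": str(rng.choice(CUISINES)),
                },
            )
        )

    users: list[UserProfile] = []
    for i in range(n_users):
        # each user weighs the four preference criteria via a consistent
        # pairwise comparison matrix built from a Dirichlet draw
        w = rng.dirichlet(np.full(4, 3.0))
        pairwise = (w[:, None] / w[None, :]).tolist()
        constraints: list[str] = []
        if rng.random() < constraint_fraction:
            constraints = [str(rng.choice(["gluten_free", "low_sodium", "low_sugar"]))]
        users.append(
            UserProfile(
                user_id=f"u{i:04d}",
                demographics={
                    "age": int(rng.integers(18, 80)),
                    "sex": str(rng.choice(["female", "male"])),
                },
                hard_constraints=constraints,
                criteria_prefs={
                    "pairwise": pairwise,
                    "order": ["nutrition", "taste", "cost", "convenience"],
                },
            )
        )

    user_latent = rng.normal(0.0, 1.0, size=(n_users, k_true))
    meal_latent = rng.normal(0.0, 1.0, size=(n_meals, k_true))
    user_bias = rng.normal(0.0, USER_BIAS_SD, size=n_users)
    meal_bias = rng.normal(0.0, MEAL_BIAS_SD, size=n_meals)

    world = SyntheticWorld(
        meals=meals,
        users=users,
        user_latent=user_latent,
        meal_latent=meal_latent,
        user_bias=user_bias,
        meal_bias=meal_bias,
        noise_sd=noise_sd,
        seed=seed,
    )

    mask = rng.random((n_users, n_meals)) < density
    utilities = world.utility_matrix()
    noise = rng.normal(0.0, noise_sd, size=mask.shape)
    ratings = np.clip(np.round(1.0 + 4.0 * utilities + noise), 1, 5).astype(int)
    interactions: list[Interaction] = []
    timestamp = 0
    for i in range(n_users):
        for j in range(n_meals):
            if mask[i, j]:
                interactions.append(
                    Interaction(
                        user_id=users[i].user_id,
                        meal_id=meals[j].meal_id,
                        rating=int(ratings[i, j]),
                        timestamp=timestamp,
                    )
                )
                timestamp += 1

    unrated = n_meals - len({i.meal_id for i in interactions})
    if unrated:
        logger.warning(
            "generate_world: %d meal(s) received no ratings at density %.3g",
            unrated,
            density,
        )
    return world, interactions


def rating_oracle(
    world: SyntheticWorld, seed: int | None = None
) -> Callable[[str, str], int]:
    """The simulated human in the loop: a callable (user, meal) -> rating
    drawing noisy discretized ratings around the true utility.

    With ``seed`` given the oracle uses its own stream (derived from the
    world seed), so the draw sequence is independent of any other oracle.
    """
    rng = world._oracle_rng if seed is None else np.random.default_rng([world.seed, seed])

    def oracle(user_id: str, meal_id: str) -> int:
        if user_id not in world.user_index:
            raise KeyError(f"unknown user {user_id!r}")
        if meal_id not in world.meal_index:
            raise KeyError(f"unknown meal {meal_id!r}")
        return world.draw_rating(user_id, meal_id, rng)

    return oracle
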