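from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cfrl.datatypes import Interaction, Meal, NutrientProfile, UserProfile
from cfrl.synthetic import generate_world

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_meal(
    meal_id: str,
    meal_type: str = "lunch",
    sodium: float = 300.0,
    calories: float = 400.0,
    **attrs,
) -> Meal:
    return Meal(
        meal_id=meal_id,
        name=f"meal {meal_id}",
        meal_type=meal_type,
        nutrients=NutrientProfile(
            calories=calories,
            carbohydrate_g=40.0,
            sodium_mg=sodium,
            sugar_g=5.0,
            fiber_g=4.0,
            protein_g=20.0,
            fat_g=15.0,
        ),
        attributes={"cost": 8.0, "prep_minutes": 20.0, **attrs},
    )


@pytest.fixture
def tiny_catalogue() -> list[Meal]:
    return [
        make_meal("b1", "breakfast", sodium=39.0, contains_gluten=False),
        make_meal("b2", "breakfast", sodium=500.0, contains_gluten=True),
        make_meal("l1", "lunch", sodium=900.0, contains_gluten=False),
        make_meal("l2", "lunch", sodium=200.0, contains_gluten=True),
        make_meal("d1", "dinner", sodium=1280.0, contains_gluten=False),
        make_meal("d2", "dinner", sodium=450.0, contains_gluten=False),
    ]


@pytest.fixture
def interactions() -> list[Interaction]:
    return [
        Interaction("u1", "b1", 4, 1),
        Interaction("u1", "l1", 5, 2),
        Interaction("u2", "b1", 3, 3),
        Interaction("u2", "d1", 2, 4),
        Interaction("u3", "l1", 4, 5),
    ]


@pytest.fixture
def profile() -> UserProfile:
    return UserProfile(user_id="u1")


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic population shared by the slower integration
    tests (30 users x 18 meals, dense enough for a usable CF fit)."""
    return generate_world(n_users=30, n_meals=18, density=0.4, seed=7)
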