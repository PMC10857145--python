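"""Core domain types: meals, nutrient vectors, users, and rating interactions.

The package works with seven per-meal nutrients throughout: energy (kcal),
carbohydrate, sugar, and fiber (g), sodium (mg), protein and fat (g).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical nutrient column order used by all tables and vectors.
NUTRIENT_FIELDS: tuple[str, ...] = (
    "calories",
    "carbohydrate_g",
    "sodium_mg",
    "sugar_g",
    "fiber_g",
    "protein_g",
    "fat_g",
)

MEAL_TYPES: tuple[str, ...] = ("breakfast", "lunch", "dinner")


@dataclass(frozen=True)
class NutrientProfile:
    """Per-meal nutrient amounts.

    All amounts must be finite and non-negative.  ``fiber_g`` exceeding
    ``carbohydrate_g`` is physically dubious but occurs on real food labels,
    so it is logged rather than rejected.
    """

    calories: float
    carbohydrate_g: float
    sodium_mg: float
    sugar_g: float
    fiber_g: float
    protein_g: float
    fat_g: float

    def __post_init__(self) -> None:
        for name in NUTRIENT_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"nutrient {name!r} must be finite and >= 0, got {value!r}"
                )
        if self.fiber_g > self.carbohydrate_g:
            logger.warning(
                "fiber_g (%.3g) exceeds carbohydrate_g (%.3g); keeping as given",
                self.fiber_g,
                self.carbohydrate_g,
            )

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in NUTRIENT_FIELDS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in NUTRIENT_FIELDS], dtype=float)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "NutrientProfile":
        return cls(**{name: float(data[name]) for name in NUTRIENT_FIELDS})


@dataclass(frozen=True)
class Meal:
    """A recommendable meal: identity, slot, nutrients, and free-form tags.

    ``attributes`` carries whatever extra per-meal facts the preference
    criteria need (cost, prep_minutes, contains_gluten, cuisine, ...).
    """

    meal_id: str
    name: str
    meal_type: str
    nutrients: NutrientProfile
    attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.meal_type not in MEAL_TYPES:
            raise ValueError(
                f"meal_type must be one of {MEAL_TYPES}, got {self.meal_type!r}"
            )


@dataclass(frozen=True)
class Interaction:
    """One explicit rating event: user rated meal on the 1-5 scale."""

    user_id: str
    meal_id: str
    rating: int
    timestamp: int = 0

    def __post_init__(self) -> None:
        if self.rating not in (1, 2, 3, 4, 5):
            raise ValueError(f"rating must be an integer in [1, 5], got {self.rating!r}")


@dataclass
class UserProfile:
    """A user: demographics, hard dietary constraints, and preference data.

    ``hard_constraints`` are names resolved against the constraint registry
    (see :mod:`cfrl.io`).  ``nutrient_targets`` optionally overrides the
    default per-nutrient trapezoid membership parameters as
    ``{nutrient: (a, b, c, d)}``.  ``criteria_prefs`` configures the
    multi-criteria preference score: either ``{"weights": {name: w}}`` or
    ``{"pairwise": [[...]], "order": [names]}`` for AHP-derived weights.
    """

    user_id: str
    demographics: dict[str, Any] = field(default_factory=dict)
    hard_constraints: list[str] = field(default_factory=list)
    nutrient_targets: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    criteria_prefs: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "user_id": self.user_id,
            "demographics": dict(self.demographics),
            "hard_constraints": list(self.hard_constraints),
            "nutrient_targets": {k: list(v) for k, v in self.nutrient_targets.items()},
            "criteria_prefs": dict(self.criteria_prefs),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "UserProfile":
        return cls(
            user_id=str(data["user_id"]),
            demographics=dict(data.get("demographics", {})),
            hard_constraints=list(data.get("hard_constraints", [])),
            nutrient_targets={
                k: tuple(float(x) for x in v)
                for k, v in data.get("nutrient_targets", {}).items()
            },
            criteria_prefs=dict(data.get("criteria_prefs", {})),
        )
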