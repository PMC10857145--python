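"""Readers, writers, preprocessing filters, and hard-constraint predicates.

Table formats (comma-separated, UTF-8, header row required):

* ``meals.csv`` — ``meal_id,name,meal_type,calories,carbohydrate_g,sodium_mg,
  sugar_g,fiber_g,protein_g,fat_g,attributes`` where ``attributes`` is a JSON
  object (may be empty).
* ``interactions.csv`` — ``user_id,meal_id,rating,timestamp``.
* ``users.json`` — a JSON list of user-profile objects.

Malformed rows are skipped with a logged warning; missing required columns
are hard errors.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import NUTRIENT_FIELDS, Interaction, Meal, NutrientProfile, UserProfile

logger = logging.getLogger(__name__)

CATALOGUE_COLUMNS = ("meal_id", "name", "meal_type") + NUTRIENT_FIELDS
INTERACTION_COLUMNS = ("user_id", "meal_id", "rating")


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    return "json" if suffix == ".json" else "csv"


def read_catalogue(path: str | Path, format: str | None = None) -> list[Meal]:
    """Read a meal catalogue from CSV or JSON.

    Rows with non-numeric or negative nutrients, or an unknown meal type,
    are skipped (counted and logged); a missing required column is an error.
    """
    fmt = _infer_format(path, format)
    if fmt == "json":
        records = json.loads(Path(path).read_text())
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        for column in CATALOGUE_COLUMNS:
            if column not in frame.columns:
                raise ValueError(f"catalogue file is missing required column {column!r}")
        records = frame.to_dict(orient="records")

    meals: list[Meal] = []
    skipped = 0
    for row in records:
        try:
            nutrients = NutrientProfile(
                **{name: float(row[name]) for name in NUTRIENT_FIELDS}
            )
            attrs_raw = row.get("attributes", "") or "{}"
            attributes = attrs_raw if isinstance(attrs_raw, dict) else json.loads(attrs_raw)
            meals.append(
                Meal(
                    meal_id=str(row["meal_id"]),
                    name=str(row["name"]),
                    meal_type=str(row["meal_type"]),
                    nutrients=nutrients,
                    attributes=attributes,
                )
            )
        except (ValueError, KeyError, json.JSONDecodeError) as exc:
            skipped += 1
            logger.warning("skipping malformed catalogue row %r: %s", row.get("meal_id"), exc)
    if skipped:
        logger.warning("read_catalogue: skipped %d malformed row(s)", skipped)
    seen: set[str] = set()
    for meal in meals:
        if meal.meal_id in seen:
            raise ValueError(f"duplicate meal_id {meal.meal_id!r} in catalogue")
        seen.add(meal.meal_id)
    return meals


def write_catalogue(meals: Sequence[Meal], path: str | Path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    rows = []
    for meal in meals:
        row: dict = {"meal_id": meal.meal_id, "name": meal.name, "meal_type": meal.meal_type}
        row.update(meal.nutrients.as_dict())
        row["attributes"] = meal.attributes if fmt == "json" else json.dumps(meal.attributes)
        rows.append(row)
    if fmt == "json":
        Path(path).write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=list(CATALOGUE_COLUMNS) + ["attributes"]).to_csv(
            path, index=False
        )


def deduplicate_interactions(interactions: Iterable[Interaction]) -> list[Interaction]:
    """Keep at most one rating per (user, meal): the one with the latest
    timestamp (last-seen wins on timestamp ties), i.e. the current opinion."""
    latest: dict[tuple[str, str], Interaction] = {}
    for inter in interactions:
        key = (inter.user_id, inter.meal_id)
        if key not in latest or inter.timestamp >= latest[key].timestamp:
            latest[key] = inter
    return list(latest.values())


def read_interactions(path: str | Path) -> list[Interaction]:
    """Read user-meal ratings from CSV; out-of-range ratings are rejected
    per row and duplicate (user, meal) pairs keep the latest timestamp."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in INTERACTION_COLUMNS:
        if column not in frame.columns:
            raise ValueError(f"interactions file is missing required column {column!r}")
    rows: list[Interaction] = []
    rejected = 0
    for row in frame.to_dict(orient="records"):
        try:
            rating = int(float(row["rating"]))
            timestamp = int(float(row.get("timestamp", 0) or 0))
            rows.append(
                Interaction(
                    user_id=str(row["user_id"]),
                    meal_id=str(row["meal_id"]),
                    rating=rating,
                    timestamp=timestamp,
                )
            )
        except ValueError as exc:
            rejected += 1
            logger.warning("rejecting interaction row %r: %s", row, exc)
    if rejected:
        logger.warning("read_interactions: rejected %d row(s)", rejected)
    return deduplicate_interactions(rows)


def write_interactions(interactions: Sequence[Interaction], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "user_id": i.user_id,
                "meal_id": i.meal_id,
                "rating": i.rating,
                "timestamp": i.timestamp,
            }
            for i in interactions
        ],
        columns=["user_id", "meal_id", "rating", "timestamp"],
    ).to_csv(path, index=False)


def read_users(path: str | Path) -> list[UserProfile]:
    return [UserProfile.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_users(users: Sequence[UserProfile], path: str | Path) -> None:
    Path(path).write_text(json.dumps([u.to_dict() for u in users], indent=1))


def filter_min_distinct_raters(
    interactions: Sequence[Interaction],
    catalogue: Sequence[Meal],
    min_raters: int = 10,
) -> tuple[list[Interaction], list[Meal]]:
    """Keep only meals rated by at least ``min_raters`` *distinct* users,
    together with their interactions.

    This mirrors the standard engagement filter for sparse rating dumps:
    repeat ratings by the same user do not count toward the threshold.
    """
    if min_raters < 1:
        raise ValueError("min_raters must be >= 1")
    raters: dict[str, set[str]] = {}
    for inter in interactions:
        raters.setdefault(inter.meal_id, set()).add(inter.user_id)
    kept_ids = {meal_id for meal_id, users in raters.items() if len(users) >= min_raters}
    kept_meals = [meal for meal in catalogue if meal.meal_id in kept_ids]
    kept_inter = [inter for inter in interactions if inter.meal_id in kept_ids]
    logger.info(
        "filter_min_distinct_raters(min=%d): kept %d/%d meals, %d/%d interactions",
        min_raters,
        len(kept_meals),
        len(catalogue),
        len(kept_inter),
        len(interactions),
    )
    return kept_inter, kept_meals


def train_test_split(
    interactions: Sequence[Interaction],
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[list[Interaction], list[Interaction]]:
    """Uniform per-interaction random partition, reproducible for a seed."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(interactions))
    n_train = int(round(train_frac * len(interactions)))
    train_idx = set(order[:n_train].tolist())
    train = [interactions[i] for i in range(len(interactions)) if i in train_idx]
    test = [interactions[i] for i in range(len(interactions)) if i not in train_idx]
    return train, test


# ---------------------------------------------------------------------------
# Hard dietary constraints
# ---------------------------------------------------------------------------
# The named predicates below give the constraint tags concrete, documented
# numeric cut-offs.  Thresholds are per meal.

LOW_SODIUM_MG = 600.0
LOW_SUGAR_G = 10.0
LOW_CALORIE_KCAL = 500.0

CONSTRAINT_REGISTRY: dict[str, Callable[[Meal], bool]] = {
    "gluten_free": lambda m: not bool(m.attributes.get("contains_gluten", False)),
    "vegetarian": lambda m: bool(m.attributes.get("vegetarian", False)),
    "low_sodium": lambda m: m.nutrients.sodium_mg <= LOW_SODIUM_MG,
    "low_sugar": lambda m: m.nutrients.sugar_g <= LOW_SUGAR_G,
    "low_calorie": lambda m: m.nutrients.calories <= LOW_CALORIE_KCAL,
}


def apply_hard_constraints(catalogue: Sequence[Meal], profile: UserProfile) -> list[Meal]:
    """Filter the catalogue to meals satisfying every constraint tag on the
    profile; preserves catalogue order.  Unknown tags are hard errors."""
    predicates = []
    for tag in profile.hard_constraints:
        if tag not in CONSTRAINT_REGISTRY:
            raise ValueError(
                f"unknown hard constraint {tag!r}; known: {sorted(CONSTRAINT_REGISTRY)}"
            )
        predicates.append(CONSTRAINT_REGISTRY[tag])
    return [meal for meal in catalogue if all(p(meal) for p in predicates)]
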