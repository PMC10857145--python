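"""Fuzzy nutrient adequacy: trapezoidal memberships and the Prerow value (PV).

Each nutrient amount ``x`` is mapped to a membership ``mu(x)`` in [0, 1] by a
trapezoid (a, b, c, d): zero outside [a, d], one on the plateau [b, c], and
linear on the ramps.  The PV aggregates the per-nutrient memberships into a
single nutritional-balance score in [0, 1]:

    PV = mu_min - (1/n) * sum_{i != i_min} (1 - mu_i)

i.e. the worst nutrient sets the ceiling and every other deficient nutrient
subtracts its average shortfall.  PV = 1 exactly when every membership is 1.
A meal scoring >= 0.7 is conventionally "acceptable" and >= 0.9 "optimal".

A multiplicative variant (``mode="reciprocal"``),
``PV = mu_min * (1/n) * sum_{i != i_min} (1/mu_i - 1)``, is kept for audit
purposes; it is *not* the default because it assigns 0 to a perfectly
adequate meal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .datatypes import NUTRIENT_FIELDS, Meal, UserProfile

logger = logging.getLogger(__name__)

MU_FLOOR = 1e-6  # memberships are raised to this before use (division safety)


@dataclass(frozen=True)
class MembershipSpec:
    """Trapezoid parameters a <= b <= c <= d in the nutrient's own units."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"require a <= b <= c <= d, got {(self.a, self.b, self.c, self.d)}")


@dataclass(frozen=True)
class PvResult:
    pv: float
    memberships: dict[str, float]
    n: int
    worst_nutrient: str | None


def membership(value: float, spec: MembershipSpec) -> float:
    """Evaluate the trapezoidal membership of a nutrient amount."""
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"nutrient value must be finite and >= 0, got {value!r}")
    if value < spec.a or value > spec.d:
        return 0.0
    if spec.b <= value <= spec.c:
        return 1.0
    if value < spec.b:  # rising ramp; b > a here since value in (a, b)
        return (value - spec.a) / (spec.b - spec.a)
    return (spec.d - value) / (spec.d - spec.c)  # falling ramp, d > c


def prerow_value(
    memberships: Sequence[float] | Mapping[str, float],
    floor: float = MU_FLOOR,
    mode: str = "deficit",
) -> PvResult:
    """Aggregate per-nutrient memberships into the PV score.

    ``mode="deficit"`` (default) computes
    ``mu_min - (1/n) * sum_{i != i_min}(1 - mu_i)`` clipped to [0, 1];
    ``mode="reciprocal"`` computes the multiplicative variant (see module
    docstring).  Ties for the minimum resolve to the first nutrient.
    """
    if isinstance(memberships, Mapping):
        names = list(memberships.keys())
        mu = np.asarray([memberships[k] for k in names], dtype=float)
    else:
        mu = np.asarray(memberships, dtype=float)
        names = [str(i) for i in range(mu.size)]
    if mu.size == 0:
        raise ValueError("membership list must be non-empty")
    if np.any(~np.isfinite(mu)) or np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("memberships must lie in [0, 1]")
    mu = np.maximum(mu, floor)
    i_min = int(np.argmin(mu))
    others = np.delete(mu, i_min)
    n = mu.size
    if mode == "deficit":
        pv = mu[i_min] - np.sum(1.0 - others) / n
    elif mode == "reciprocal":
        pv = mu[i_min] * np.sum(1.0 / others - 1.0) / n
    else:
        raise ValueError(f"unknown PV mode {mode!r}")
    pv = float(np.clip(pv, 0.0, 1.0))
    return PvResult(
        pv=pv,
        memberships={names[i]: float(mu[i]) for i in range(n)},
        n=n,
        worst_nutrient=names[i_min],
    )


def classify_pv(pv: float) -> str:
    """Map a PV score to its conventional band."""
    if pv >= 0.9:
        return "optimal"
    if pv >= 0.7:
        return "acceptable"
    return "below acceptable"


# ---------------------------------------------------------------------------
# Default per-meal membership windows
# ---------------------------------------------------------------------------
# Derived from common adult reference intakes spread over three meals; wide
# plateaus, generous ramps.  Sodium and sugar have no lower ramp (less is
# fine); fiber and protein reward any reasonable amount.  All overridable per
# user via ``UserProfile.nutrient_targets`` or a YAML spec file.

DEFAULT_MEMBERSHIP_SPECS: dict[str, MembershipSpec] = {
    "calories": MembershipSpec(100.0, 250.0, 700.0, 1000.0),
    "carbohydrate_g": MembershipSpec(5.0, 20.0, 80.0, 130.0),
    "sodium_mg": MembershipSpec(0.0, 0.0, 600.0, 1500.0),
    "sugar_g": MembershipSpec(0.0, 0.0, 15.0, 40.0),
    "fiber_g": MembershipSpec(0.0, 2.0, 25.0, 50.0),
    "protein_g": MembershipSpec(2.0, 10.0, 45.0, 90.0),
    "fat_g": MembershipSpec(2.0, 8.0, 30.0, 60.0),
}


def resolve_membership_specs(
    profile: UserProfile | None = None,
    defaults: Mapping[str, MembershipSpec] | None = None,
    allow_defaults: bool = True,
) -> dict[str, MembershipSpec]:
    """Merge a user's nutrient targets over the shipped defaults."""
    base = dict(DEFAULT_MEMBERSHIP_SPECS if defaults is None else defaults)
    if profile is not None:
        for name, abcd in profile.nutrient_targets.items():
            base[name] = MembershipSpec(*abcd)
    missing = [name for name in NUTRIENT_FIELDS if name not in base]
    if missing:
        raise ValueError(f"no membership spec for nutrient(s) {missing}")
    if not allow_defaults and (profile is None or not profile.nutrient_targets):
        raise ValueError("defaults disabled and profile supplies no nutrient targets")
    return base


def score_meal_nutrition(
    meal: Meal,
    profile: UserProfile | None = None,
    specs: Mapping[str, MembershipSpec] | None = None,
    mode: str = "deficit",
) -> PvResult:
    """PV of one meal under the profile's (or default) membership windows."""
    resolved = resolve_membership_specs(profile, specs)
    mu = {
        name: membership(getattr(meal.nutrients, name), resolved[name])
        for name in NUTRIENT_FIELDS
    }
    return prerow_value(mu, mode=mode)


def score_day_nutrition(
    meals: Sequence[Meal],
    profile: UserProfile | None = None,
    specs: Mapping[str, MembershipSpec] | None = None,
) -> PvResult:
    """Daily aggregate PV: nutrient totals scored against the per-meal
    windows scaled by the number of meals."""
    if not meals:
        raise ValueError("need at least one meal")
    resolved = resolve_membership_specs(profile, specs)
    k = float(len(meals))
    totals = {
        name: sum(getattr(m.nutrients, name) for m in meals) for name in NUTRIENT_FIELDS
    }
    mu = {
        name: membership(
            totals[name],
            MembershipSpec(
                resolved[name].a * k, resolved[name].b * k,
                resolved[name].c * k, resolved[name].d * k,
            ),
        )
        for name in NUTRIENT_FIELDS
    }
    return prerow_value(mu)


def load_membership_specs(path: str | Path) -> dict[str, MembershipSpec]:
    """Read per-nutrient (a, b, c, d) trapezoids from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text())
    return {name: MembershipSpec(*[float(x) for x in abcd]) for name, abcd in raw.items()}


def dump_membership_specs(specs: Mapping[str, MembershipSpec], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({k: [v.a, v.b, v.c, v.d] for k, v in specs.items()})
    )
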