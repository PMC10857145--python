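"""Reward shaping: the scalar training signal for the recommendation agent.

The reward is a convex combination of three bounded components:

    r = w_r * ru + w_n * n + w_p * p

where ``ru`` is the user's rating mapped affinely from the 1-5 scale onto
[0, 1], ``n`` is the fuzzy nutrition score (PV), and ``p`` is the TOPSIS
preference score.  With normalized weights the reward stays in [0, 1].

Default weights put 0.4 on nutrition and 0.3 each on rating and preference.
"""
from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class RewardWeights:
    """Non-negative component weights; normalized to sum to 1 on creation."""

    w_r: float = 0.3
    w_n: float = 0.4
    w_p: float = 0.3

    def __post_init__(self) -> None:
        for name in ("w_r", "w_n", "w_p"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        total = self.w_r + self.w_n + self.w_p
        if total <= 0:
            raise ValueError("at least one reward weight must be positive")
        object.__setattr__(self, "w_r", self.w_r / total)
        object.__setattr__(self, "w_n", self.w_n / total)
        object.__setattr__(self, "w_p", self.w_p / total)


@dataclass(frozen=True)
class RewardComponents:
    """One step's logged reward breakdown, all values in [0, 1]."""

    ru: float
    n: float
    p: float
    r: float


def normalize_rating(rating: int) -> float:
    """Map a 1-5 rating onto [0, 1] affinely: 1 -> 0, 3 -> 0.5, 5 -> 1."""
    if rating not in (1, 2, 3, 4, 5):
        raise ValueError(f"rating must be an integer in [1, 5], got {rating!r}")
    return (rating - 1) / 4.0


def compose_reward(
    ru: float, n: float, p: float, weights: RewardWeights | None = None
) -> RewardComponents:
    """Weighted sum of the three components; inputs must be finite [0, 1]."""
    weights = weights or RewardWeights()
    for name, value in (("ru", ru), ("n", n), ("p", p)):
        if not math.isfinite(value):
            raise ValueError(f"reward component {name} is not finite: {value!r}")
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"reward component {name} must lie in [0, 1], got {value!r}")
    r = weights.w_r * ru + weights.w_n * n + weights.w_p * p
    return RewardComponents(ru=ru, n=n, p=p, r=r)
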