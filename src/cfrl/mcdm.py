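"""Multi-criteria preference scoring: AHP weighting and TOPSIS ranking.

Criterion weights come either directly from the user or from an AHP pairwise
comparison matrix (principal eigenvector, with the consistency ratio checked
against the standard random-index table).  Alternatives (meals) are ranked by
TOPSIS: vector-normalize the decision matrix, weight the columns, locate the
positive/negative ideal solutions per criterion direction, and score each
alternative by its relative Euclidean closeness to the worst solution,
``S_i = d_iw / (d_iw + d_ib)`` in [0, 1] (higher is better).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .datatypes import Meal, UserProfile

logger = logging.getLogger(__name__)

#: Saaty random consistency indices for matrix sizes 1..9.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45}

BENEFIT = "benefit"
COST = "cost"


@dataclass(frozen=True)
class CriterionSpec:
    """One decision criterion: its name, direction, and (relative) weight."""

    name: str
    direction: str = BENEFIT
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (BENEFIT, COST):
            raise ValueError(f"direction must be '{BENEFIT}' or '{COST}'")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def normalize_weights(criteria: Sequence[CriterionSpec]) -> list[CriterionSpec]:
    total = sum(c.weight for c in criteria)
    if total <= 0:
        raise ValueError("criterion weights must sum to a positive value")
    return [CriterionSpec(c.name, c.direction, c.weight / total) for c in criteria]


def ahp_weights(
    pairwise: np.ndarray | Sequence[Sequence[float]],
    tol: float = 1e-10,
    max_iter: int = 10_000,
    strict: bool = False,
) -> tuple[np.ndarray, float]:
    """Principal-eigenvector weights and consistency ratio of a reciprocal
    pairwise comparison matrix.

    Power iteration to ``tol``; CR = ((lambda_max - N)/(N - 1)) / RI(N).
    CR > 0.1 logs a warning, or raises in ``strict`` mode.
    """
    A = np.asarray(pairwise, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("pairwise matrix must be square")
    n = A.shape[0]
    if not 2 <= n <= 9:
        raise ValueError("pairwise matrix size must be between 2 and 9")
    if np.any(A <= 0):
        raise ValueError("pairwise comparisons must be positive")
    if not np.allclose(np.diag(A), 1.0, atol=1e-9):
        raise ValueError("pairwise matrix diagonal must be 1")
    if not np.allclose(A * A.T, 1.0, atol=1e-9):
        raise ValueError("pairwise matrix must be reciprocal (a_qp = 1/a_pq)")

    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w_new = A @ w
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    lam = float(np.mean((A @ w) / w))
    ri = RANDOM_INDEX[n]
    cr = 0.0 if ri == 0.0 else ((lam - n) / (n - 1)) / ri
    if cr > 0.1:
        msg = f"AHP consistency ratio {cr:.3f} exceeds 0.1"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return w, cr


def topsis_normalize(A: np.ndarray | Sequence[Sequence[float]]) -> np.ndarray:
    """Column-wise Euclidean (vector) normalization of the raw decision
    matrix.  All-zero columns are left at zero (callers drop them)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("decision matrix must be 2-dimensional")
    if np.any(A < 0):
        raise ValueError("decision matrix values must be non-negative")
    norms = np.sqrt(np.sum(A**2, axis=0))
    R = np.zeros_like(A)
    nonzero = norms > 0
    R[:, nonzero] = A[:, nonzero] / norms[nonzero]
    return R


@dataclass
class TopsisResult:
    scores: np.ndarray  # S_i in [0, 1], one per alternative
    ranking: np.ndarray  # alternative indices, best first (stable ties)
    weighted: np.ndarray  # t_ij
    ideal_best: np.ndarray  # A_b
    ideal_worst: np.ndarray  # A_w
    criteria: list[CriterionSpec] = field(default_factory=list)


def topsis_score(
    A: np.ndarray | Sequence[Sequence[float]],
    criteria: Sequence[CriterionSpec],
) -> TopsisResult:
    """Full TOPSIS pass over an m x n raw decision matrix.

    Degenerate cases: all-zero columns are dropped (weights renormalized);
    if every alternative is identical, all scores are 0.5.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("decision matrix must be 2-dimensional")
    if A.shape[1] != len(criteria):
        raise ValueError("one criterion spec required per column")
    criteria = normalize_weights(criteria)

    keep = np.sqrt(np.sum(A**2, axis=0)) > 0
    if not np.all(keep):
        dropped = [criteria[j].name for j in range(len(criteria)) if not keep[j]]
        logger.warning("dropping all-zero criterion column(s) %s", dropped)
        criteria = normalize_weights([c for c, k in zip(criteria, keep) if k])
        A = A[:, keep]
        if A.shape[1] == 0:
            m = A.shape[0]
            half = np.full(m, 0.5)
            return TopsisResult(half, np.arange(m), A, np.array([]), np.array([]), [])

    weights = np.array([c.weight for c in criteria])
    benefit = np.array([c.direction == BENEFIT for c in criteria])

    T = topsis_normalize(A) * weights
    best = np.where(benefit, T.max(axis=0), T.min(axis=0))
    worst = np.where(benefit, T.min(axis=0), T.max(axis=0))
    d_best = np.sqrt(np.sum((T - best) ** 2, axis=1))
    d_worst = np.sqrt(np.sum((T - worst) ** 2, axis=1))
    denom = d_best + d_worst
    scores = np.full(A.shape[0], 0.5)  # identical alternatives: indifference
    nz = denom > 0
    scores[nz] = d_worst[nz] / denom[nz]
    ranking = np.argsort(-scores, kind="stable")
    return TopsisResult(scores, ranking, T, best, worst, list(criteria))


# ---------------------------------------------------------------------------
# Preference score over a candidate meal set
# ---------------------------------------------------------------------------

#: Extractors map a meal to one raw criterion value (must be >= 0).
CriterionExtractor = Callable[[Meal], float]

DEFAULT_CRITERIA_DIRECTIONS = {
    "nutrition": BENEFIT,
    "taste": BENEFIT,
    "cost": COST,
    "convenience": COST,  # measured as preparation minutes: lower is better
}


def criteria_from_profile(
    profile: UserProfile | None,
    names: Sequence[str],
    directions: Mapping[str, str] | None = None,
) -> list[CriterionSpec]:
    """Build weighted criteria from a profile's preference data.

    Accepts direct weights (``{"weights": {...}}``) or an AHP pairwise matrix
    (``{"pairwise": [[...]], "order": [...]}``); defaults to equal weights.
    """
    directions = dict(DEFAULT_CRITERIA_DIRECTIONS if directions is None else directions)
    prefs = profile.criteria_prefs if profile is not None else {}
    if "weights" in prefs:
        weights = {str(k): float(v) for k, v in prefs["weights"].items()}
        missing = [n for n in names if n not in weights]
        if missing:
            raise ValueError(f"profile weights missing criteria {missing}")
        w = [weights[n] for n in names]
    elif "pairwise" in prefs:
        order = [str(n) for n in prefs.get("order", names)]
        if sorted(order) != sorted(names):
            raise ValueError("pairwise 'order' must name exactly the criteria in use")
        vec, _ = ahp_weights(prefs["pairwise"])
        by_name = dict(zip(order, vec))
        w = [float(by_name[n]) for n in names]
    else:
        w = [1.0] * len(names)
    specs = [
        CriterionSpec(n, directions.get(n, BENEFIT), wi) for n, wi in zip(names, w)
    ]
    return normalize_weights(specs)


def preference_score(
    meals: Sequence[Meal],
    profile: UserProfile | None,
    extractors: Mapping[str, CriterionExtractor],
    directions: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Per-meal preference score p in [0, 1]: AHP-weighted TOPSIS over the
    candidate set.  A single candidate scores 1.0 by convention."""
    if not meals:
        raise ValueError("candidate set must be non-empty")
    names = list(extractors.keys())
    if len(meals) == 1:
        logger.info("single-candidate set: preference score 1.0 by convention")
        return np.array([1.0])
    A = np.array([[extractors[n](meal) for n in names] for meal in meals], dtype=float)
    criteria = criteria_from_profile(profile, names, directions)
    return topsis_score(A, criteria).scores
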