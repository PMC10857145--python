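"""Latent-factor collaborative filtering over the user-meal rating matrix.

The observed ratings form a sparse matrix R (users x meals, values 1-5).
"SVD" in the recommender sense is realized as bias-augmented stochastic
gradient matrix factorization on the *observed* entries (Funk-style):

    r_hat(u, m) = mu + b_u + b_m + U_u . M_m,   minimized squared error + L2

which is the numerically sound counterpart of a truncated SVD when most
entries are missing.  A mean-imputed truncated-SVD variant is available via
``method="truncated"`` for comparison.  Predictions are clipped to the 1-5
rating scale; a normalized acceptance score maps that affinely onto [0, 1].

The fitted user row ``U_u`` doubles as the user's state vector for the
reinforcement-learning agent, and is updated online, one SGD step per fresh
rating, with the meal factors held fixed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .datatypes import Interaction, Meal

logger = logging.getLogger(__name__)

RATING_MIN, RATING_MAX = 1.0, 5.0


@dataclass
class RatingMatrix:
    """Sparse user x meal rating matrix with stable id <-> index maps."""

    users: list[str]
    meals: list[str]
    matrix: sp.csr_matrix  # explicit ratings; 0 = unobserved
    user_index: dict[str, int] = field(init=False)
    meal_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.user_index = {u: i for i, u in enumerate(self.users)}
        self.meal_index = {m: j for j, m in enumerate(self.meals)}

    @property
    def n_observed(self) -> int:
        return int(self.matrix.nnz)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def get(self, user_id: str, meal_id: str) -> float | None:
        value = self.matrix[self.user_index[user_id], self.meal_index[meal_id]]
        return float(value) if value != 0 else None

    def observed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        coo = self.matrix.tocoo()
        return coo.row, coo.col, coo.data


def build_matrix(
    interactions: Sequence[Interaction],
    users: Sequence[str] | None = None,
    meals: Sequence[str] | Sequence[Meal] | None = None,
) -> RatingMatrix:
    """Assemble the rating matrix from deduplicated interactions.

    Row/column universes default to the ids present in the interactions
    (sorted for stability); interactions referencing unknown meals or users
    are skipped with a warning.
    """
    if meals is not None and meals and isinstance(meals[0], Meal):
        meals = [m.meal_id for m in meals]  # type: ignore[union-attr]
    user_list = sorted({i.user_id for i in interactions}) if users is None else list(users)
    meal_list = sorted({i.meal_id for i in interactions}) if meals is None else list(meals)
    uidx = {u: i for i, u in enumerate(user_list)}
    midx = {m: j for j, m in enumerate(meal_list)}
    rows, cols, vals = [], [], []
    skipped = 0
    for inter in interactions:
        if inter.user_id not in uidx or inter.meal_id not in midx:
            skipped += 1
            continue
        rows.append(uidx[inter.user_id])
        cols.append(midx[inter.meal_id])
        vals.append(float(inter.rating))
    if skipped:
        logger.warning("build_matrix: skipped %d interaction(s) with unknown ids", skipped)
    matrix = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(user_list), len(meal_list)), dtype=float
    )
    return RatingMatrix(user_list, meal_list, matrix)


@dataclass
class LatentFactors:
    """Fitted factorization: R ~ mu + b_u + b_m + U M^T."""

    U: np.ndarray  # users x k
    M: np.ndarray  # meals x k
    bu: np.ndarray
    bm: np.ndarray
    mu: float
    k: int
    users: list[str]
    meals: list[str]
    user_index: dict[str, int] = field(init=False)
    meal_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.user_index = {u: i for i, u in enumerate(self.users)}
        self.meal_index = {m: j for j, m in enumerate(self.meals)}

    def copy(self) -> "LatentFactors":
        return LatentFactors(
            self.U.copy(), self.M.copy(), self.bu.copy(), self.bm.copy(),
            self.mu, self.k, list(self.users), list(self.meals),
        )

    def user_state(self, user_id: str) -> np.ndarray:
        """The user's latent row — the CF-based RL state vector."""
        return self.U[self.user_index[user_id]].copy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            U=self.U, M=self.M, bu=self.bu, bm=self.bm, mu=np.array([self.mu]),
        )
        path.with_suffix(".json").write_text(
            json.dumps({"schema": 1, "k": self.k, "users": self.users, "meals": self.meals})
        )

    @classmethod
    def load(cls, path: str | Path) -> "LatentFactors":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta.get("schema") != 1:
            raise ValueError("unsupported checkpoint schema")
        return cls(
            arrays["U"], arrays["M"], arrays["bu"], arrays["bm"],
            float(arrays["mu"][0]), int(meta["k"]), meta["users"], meta["meals"],
        )


def fit_svd(
    R: RatingMatrix,
    k: int = 16,
    epochs: int = 30,
    lr: float = 0.01,
    reg: float = 0.05,
    seed: int = 0,
    init_sd: float = 0.1,
    method: str = "sgd",
) -> LatentFactors:
    """Fit the latent-factor model on the observed entries.

    ``method="sgd"`` (default) runs epoch-wise shuffled SGD with bias terms;
    ``method="truncated"`` mean-imputes the matrix and takes a classical
    truncated SVD (no biases beyond the global mean).  Deterministic for a
    fixed seed.
    """
    n_users, n_meals = R.shape
    if k < 1 or k >= min(n_users, n_meals):
        raise ValueError(f"k must satisfy 1 <= k < min(n_users, n_meals) = {min(n_users, n_meals)}")
    rows, cols, vals = R.observed()
    if len(vals) == 0:
        raise ValueError("rating matrix has no observed entries")
    mu = float(np.mean(vals))

    if method == "truncated":
        dense = np.full((n_users, n_meals), mu)
        dense[rows, cols] = vals
        u, s, vt = sp.linalg.svds(sp.csr_matrix(dense - mu), k=k)
        order = np.argsort(-s)
        u, s, vt = u[:, order], s[order], vt[order]
        return LatentFactors(
            U=u * np.sqrt(s), M=(vt.T * np.sqrt(s)),
            bu=np.zeros(n_users), bm=np.zeros(n_meals),
            mu=mu, k=k, users=list(R.users), meals=list(R.meals),
        )
    if method != "sgd":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    U = rng.normal(0.0, init_sd, size=(n_users, k))
    M = rng.normal(0.0, init_sd, size=(n_meals, k))
    bu = np.zeros(n_users)
    bm = np.zeros(n_meals)
    n_obs = len(vals)
    for _ in range(epochs):
        for idx in rng.permutation(n_obs):
            u_i, m_j, r = rows[idx], cols[idx], vals[idx]
            pred = mu + bu[u_i] + bm[m_j] + U[u_i] @ M[m_j]
            err = r - pred
            bu[u_i] += lr * (err - reg * bu[u_i])
            bm[m_j] += lr * (err - reg * bm[m_j])
            u_row = U[u_i].copy()
            U[u_i] += lr * (err * M[m_j] - reg * u_row)
            M[m_j] += lr * (err * u_row - reg * M[m_j])
    return LatentFactors(U, M, bu, bm, mu, k, list(R.users), list(R.meals))


def _raw_prediction(factors: LatentFactors, u: int | None, m: int | None) -> float:
    pred = factors.mu
    if u is not None:
        pred += factors.bu[u]
    if m is not None:
        pred += factors.bm[m]
    if u is not None and m is not None:
        pred += float(factors.U[u] @ factors.M[m])
    return pred


def predict_acceptance(
    factors: LatentFactors, user_id: str, meal_id: str
) -> tuple[float, float]:
    """Predicted rating (clipped to [1, 5]) and normalized acceptance in
    [0, 1].  Cold users/meals fall back to the available bias terms."""
    u = factors.user_index.get(user_id)
    m = factors.meal_index.get(meal_id)
    if u is None or m is None:
        logger.info("cold prediction for (%s, %s): bias-only fallback", user_id, meal_id)
    rating = float(np.clip(_raw_prediction(factors, u, m), RATING_MIN, RATING_MAX))
    return rating, (rating - RATING_MIN) / (RATING_MAX - RATING_MIN)


def predict_user_vector(factors: LatentFactors, user_id: str) -> np.ndarray:
    """Predicted (clipped) ratings for one user across every known meal."""
    u = factors.user_index.get(user_id)
    if u is None:
        raw = factors.mu + factors.bm
    else:
        raw = factors.mu + factors.bu[u] + factors.bm + factors.M @ factors.U[u]
    return np.clip(raw, RATING_MIN, RATING_MAX)


def update_user_latent(
    factors: LatentFactors,
    user_id: str,
    meal_id: str,
    rating: float,
    eta: float = 0.05,
    reg: float = 0.0,
) -> np.ndarray:
    """One online SGD step on the user's latent row for a fresh rating.

    ``U_u <- U_u + eta * (err * M_m - reg * U_u)`` with the meal factors and
    all biases held fixed; only row ``u`` of ``U`` changes.  Returns the
    updated row.  Unknown meals are a warned no-op.
    """
    if not RATING_MIN <= rating <= RATING_MAX:
        raise ValueError(f"rating must lie in [1, 5], got {rating!r}")
    u = factors.user_index.get(user_id)
    if u is None:
        raise KeyError(f"unknown user {user_id!r}")
    m = factors.meal_index.get(meal_id)
    if m is None:
        logger.warning("update_user_latent: unknown meal %r; no-op", meal_id)
        return factors.U[u].copy()
    pred = _raw_prediction(factors, u, m)
    err = rating - pred
    factors.U[u] += eta * (err * factors.M[m] - reg * factors.U[u])
    return factors.U[u].copy()
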