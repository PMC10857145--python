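from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

from cfrl.cf import (
    LatentFactors,
    RatingMatrix,
    build_matrix,
    fit_svd,
    predict_acceptance,
    predict_user_vector,
    update_user_latent,
)
from cfrl.datatypes import Interaction
from cfrl.io import train_test_split


def rank2_matrix(seed: int = 0) -> RatingMatrix:
    """A complete noiseless rank-2 (plus constant) matrix inside [1, 5]."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(-1, 1, (5, 2))
    B = rng.uniform(-1, 1, (6, 2))
    dense = 3.0 + A @ B.T
    return RatingMatrix(
        [f"u{i}" for i in range(5)], [f"m{j}" for j in range(6)], sp.csr_matrix(dense)
    )


class TestBuildMatrix:
    def test_observed_entries_and_index_round_trip(self, interactions):
        R = build_matrix(interactions)
        assert R.shape == (3, 3)
        assert R.n_observed == 5
        assert R.get("u1", "l1") == 5.0
        assert R.get("u3", "b1") is None

    def test_unknown_ids_skipped_with_warning(self, interactions, caplog):
        with caplog.at_level("WARNING"):
            R = build_matrix(interactions, users=["u1", "u2"], meals=["b1", "l1"])
        assert R.n_observed == 3
        assert any("unknown ids" in r.message for r in caplog.records)

    def test_empty_interactions_give_valid_empty_matrix(self):
        R = build_matrix([], users=["u1"], meals=["m1"])
        assert R.n_observed == 0 and R.shape == (1, 1)


class TestFitSvd:
    def test_noiseless_rank2_recovery(self):
        R = rank2_matrix()
        factors = fit_svd(R, k=2, epochs=500, lr=0.05, reg=0.0, seed=0)
        dense = R.matrix.toarray()
        pred = factors.mu + factors.bu[:, None] + factors.bm[None, :] + factors.U @ factors.M.T
        assert np.sqrt(np.mean((pred - dense) ** 2)) < 1e-2

    def test_constant_matrix_learned_by_biases(self):
        dense = np.full((4, 5), 4.0)
        R = RatingMatrix(
            [f"u{i}" for i in range(4)], [f"m{j}" for j in range(5)], sp.csr_matrix(dense)
        )
        factors = fit_svd(R, k=2, epochs=100, lr=0.05, reg=0.0, seed=1)
        rating, _ = predict_acceptance(factors, "u0", "m3")
        assert rating == pytest.approx(4.0, abs=1e-2)

    def test_seeded_fit_is_bitwise_identical(self, interactions):
        R = build_matrix(interactions)
        a = fit_svd(R, k=2, epochs=5, seed=42)
        b = fit_svd(R, k=2, epochs=5, seed=42)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.M, b.M)
        assert np.array_equal(a.bu, b.bu) and np.array_equal(a.bm, b.bm)

    def test_k_out_of_range_rejected(self, interactions):
        R = build_matrix(interactions)
        with pytest.raises(ValueError, match="k must"):
            fit_svd(R, k=3)

    def test_truncated_variant_reconstructs_complete_matrix(self):
        # the mean-centered residual of a rank-2-plus-constant matrix has
        # rank at most 3, so a 3-component truncated SVD is exact
        R = rank2_matrix()
        factors = fit_svd(R, k=3, method="truncated")
        pred = factors.mu + factors.U @ factors.M.T
        assert np.sqrt(np.mean((pred - R.matrix.toarray()) ** 2)) < 1e-8


class TestPrediction:
    def test_predictions_clipped_and_normalized(self):
        factors = fit_svd(rank2_matrix(), k=2, epochs=50, seed=0)
        for user in factors.users:
            for meal in factors.meals:
                rating, norm = predict_acceptance(factors, user, meal)
                assert 1.0 <= rating <= 5.0
                assert norm == pytest.approx((rating - 1) / 4)

    def test_cold_user_falls_back_to_meal_bias(self):
        factors = fit_svd(rank2_matrix(), k=2, epochs=50, seed=0)
        rating, _ = predict_acceptance(factors, "stranger", "m0")
        expected = np.clip(factors.mu + factors.bm[0], 1, 5)
        assert rating == pytest.approx(expected)

    def test_held_in_entries_recovered(self):
        R = rank2_matrix()
        factors = fit_svd(R, k=2, epochs=500, lr=0.05, reg=0.0, seed=0)
        dense = R.matrix.toarray()
        for i, user in enumerate(factors.users):
            for j, meal in enumerate(factors.meals):
                rating, _ = predict_acceptance(factors, user, meal)
                assert rating == pytest.approx(dense[i, j], abs=0.1)

    def test_user_vector_matches_scalar_prediction(self):
        factors = fit_svd(rank2_matrix(), k=2, epochs=20, seed=0)
        vec = predict_user_vector(factors, "u1")
        for j, meal in enumerate(factors.meals):
            assert vec[j] == pytest.approx(predict_acceptance(factors, "u1", meal)[0])


class TestOnlineUpdate:
    def test_zero_error_zero_reg_is_fixed_point(self):
        factors = fit_svd(rank2_matrix(), k=2, epochs=200, lr=0.05, reg=0.0, seed=0)
        rating, _ = predict_acceptance(factors, "u0", "m0")
        before = factors.U.copy()
        update_user_latent(factors, "u0", "m0", rating, eta=0.1, reg=0.0)
        assert np.allclose(factors.U, before, atol=1e-6)

    def test_repeated_updates_converge_monotonically(self):
        factors = fit_svd(rank2_matrix(), k=2, epochs=50, seed=0)
        target = 5.0
        errors = []
        for _ in range(60):
            pred, _ = predict_acceptance(factors, "u2", "m4")
            errors.append(abs(target - pred))
            update_user_latent(factors, "u2", "m4", target, eta=0.05, reg=0.0)
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < errors[0]

    def test_update_touches_only_that_user_row(self):
        factors = fit_svd(rank2_matrix(), k=2, epochs=20, seed=0)
        U_before, M_before = factors.U.copy(), factors.M.copy()
        update_user_latent(factors, "u1", "m2", 5, eta=0.1)
        changed = np.any(factors.U != U_before, axis=1)
        assert list(changed) == [False, True, False, False, False]
        assert np.array_equal(factors.M, M_before)

    def test_unknown_meal_is_warned_noop(self, caplog):
        factors = fit_svd(rank2_matrix(), k=2, epochs=5, seed=0)
        before = factors.U.copy()
        with caplog.at_level("WARNING"):
            update_user_latent(factors, "u0", "nope", 3)
        assert np.array_equal(factors.U, before)


class TestRecoveryOnSyntheticData:
    def test_beats_global_mean_on_held_out_ratings(self, small_world):
        world, interactions = small_world
        train, test = train_test_split(interactions, 0.7, seed=7)
        R = build_matrix(
            train, [u.user_id for u in world.users], [m.meal_id for m in world.meals]
        )
        factors = fit_svd(R, k=4, epochs=40, seed=7)
        mean = np.mean([i.rating for i in train])
        preds = np.array(
            [predict_acceptance(factors, i.user_id, i.meal_id)[0] for i in test]
        )
        truth = np.array([i.rating for i in test])
        rmse_model = np.sqrt(np.mean((preds - truth) ** 2))
        rmse_mean = np.sqrt(np.mean((mean - truth) ** 2))
        assert rmse_model < rmse_mean

    def test_predictions_track_true_utility_ordering(self, small_world):
        world, interactions = small_world
        R = build_matrix(
            interactions, [u.user_id for u in world.users], [m.meal_id for m in world.meals]
        )
        factors = fit_svd(R, k=4, epochs=40, seed=7)
        pred = np.vstack([predict_user_vector(factors, u.user_id) for u in world.users])
        rho = scipy.stats.spearmanr(pred.ravel(), world.utility_matrix().ravel()).statistic
        assert rho > 0.7  # dense small world: ordering clearly recovered


def test_checkpoint_round_trip(tmp_path, interactions):
    R = build_matrix(interactions)
    factors = fit_svd(R, k=2, epochs=5, seed=0)
    factors.save(tmp_path / "ckpt")
    back = LatentFactors.load(tmp_path / "ckpt")
    assert np.array_equal(back.U, factors.U)
    assert back.users == factors.users and back.k == factors.k
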