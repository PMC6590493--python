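"""Level translation, pairwise machinery, calibration, and estimators."""

import numpy as np
import pytest

from cellquant.errors import (
    EmptyPairSetError,
    InvalidInputError,
    InvalidParameterError,
    InvalidTrainingSetError,
)
from cellquant.metrics import kendall_tau_b
from cellquant.regress import (
    DEFAULT_LEVEL_MAP,
    build_adjacent_pairs,
    cellularity_to_level,
    huber_loss,
    knn_calibrate,
    level_to_cellularity,
    linear_correction,
    rank_loss,
    ranknet_pair_prob,
    train_estimator,
)


class TestLevelMap:
    @pytest.mark.parametrize(
        "cellularity,level",
        [(0.0, 0), (0.01, 1), (0.10, 10), (0.15, 11), (0.90, 26),
         (0.91, 27), (1.00, 36)],
    )
    def test_grid_values(self, cellularity, level):
        assert cellularity_to_level(cellularity) == level

    def test_round_trip_on_all_grid_values(self):
        for c in DEFAULT_LEVEL_MAP.grid:
            assert level_to_cellularity(cellularity_to_level(c)) == pytest.approx(c)

    def test_snapping_prefers_lower_bin_on_ties(self):
        # 0.125 is equidistant between 0.10 (level 10) and 0.15 (level 11)
        assert cellularity_to_level(0.125) == 10

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            cellularity_to_level(1.2)

    def test_map_has_37_levels(self):
        assert DEFAULT_LEVEL_MAP.n_levels == 37


class TestHuberLoss:
    def test_zero_residual(self):
        assert huber_loss([0.0]) == 0.0

    def test_quadratic_branch(self):
        assert huber_loss([0.5], delta=1.0) == pytest.approx(0.125)

    def test_linear_branch(self):
        assert huber_loss([2.0], delta=1.0) == pytest.approx(1.5)

    def test_invalid_delta(self):
        with pytest.raises(InvalidParameterError):
            huber_loss([1.0], delta=0.0)


class TestAdjacentPairs:
    def test_chain_of_singletons(self):
        pairs = build_adjacent_pairs([0, 1, 2])
        assert {(p.index_low, p.index_high) for p in pairs} == {(0, 1), (1, 2)}

    def test_cross_count(self):
        pairs = build_adjacent_pairs([0, 0, 1, 1, 1])
        assert len(pairs) == 6  # 2 x 3 cross pairs

    def test_level_difference_is_one(self):
        levels = np.array([3, 5, 4, 4, 3, 6])
        for p in build_adjacent_pairs(levels):
            assert levels[p.index_high] - levels[p.index_low] == 1

    def test_single_level_rejected(self):
        with pytest.raises(EmptyPairSetError):
            build_adjacent_pairs([5, 5, 5])


class TestRankNetProbability:
    def test_equal_scores_give_half(self):
        assert ranknet_pair_prob(1.0, 1.0) == pytest.approx(0.5)

    def test_log3_margin_gives_three_quarters(self):
        assert ranknet_pair_prob(np.log(3), 0.0, k=1.0) == pytest.approx(0.75)

    def test_complementarity(self, rng):
        a, b = rng.normal(size=2)
        assert ranknet_pair_prob(a, b) + ranknet_pair_prob(b, a) == pytest.approx(1.0)


class TestRankLoss:
    def test_all_equal_scores_cost_ln2_per_pair(self):
        pairs = build_adjacent_pairs([0, 1, 2])
        assert rank_loss(np.zeros(3), pairs) == pytest.approx(len(pairs) * np.log(2))

    def test_satisfied_pairs_beat_chance(self):
        pairs = build_adjacent_pairs([0, 1, 2])
        assert rank_loss(np.array([0.0, 2.0, 4.0]), pairs) < len(pairs) * np.log(2)

    def test_single_pair_closed_form(self):
        # P = 0.75 requires score gap ln 3
        pairs = build_adjacent_pairs([0, 1])
        loss = rank_loss(np.array([0.0, np.log(3)]), pairs)
        assert loss == pytest.approx(-np.log(0.75))

    def test_invariant_to_constant_shift(self, rng):
        levels = rng.integers(0, 4, size=12)
        levels[:4] = [0, 1, 2, 3]
        pairs = build_adjacent_pairs(levels)
        s = rng.normal(size=12)
        assert rank_loss(s, pairs) == pytest.approx(rank_loss(s + 5.0, pairs))


class TestKnnCalibration:
    def test_exact_match_with_k1(self):
        out = knn_calibrate(0.4, [0.1, 0.4, 0.9], [0.2, 0.5, 0.8], k=1)
        assert out == 0.5

    def test_constant_labels_return_constant(self, rng):
        scores = rng.normal(size=50)
        out = knn_calibrate(0.0, scores, np.full(50, 0.3), k=30)
        assert out == pytest.approx(0.3)

    def test_matches_exhaustive_sort_oracle(self, rng):
        train_s = rng.normal(size=100)
        train_c = rng.uniform(size=100)
        queries = rng.normal(size=10)
        got = knn_calibrate(queries, train_s, train_c, k=30)
        for q, g in zip(queries, got):
            order = sorted(range(100), key=lambda i: (abs(train_s[i] - q), i))
            assert g == pytest.approx(np.mean(train_c[order[:30]]))

    def test_output_within_training_label_range(self, rng):
        train_s, train_c = rng.normal(size=40), rng.uniform(0.2, 0.6, size=40)
        out = knn_calibrate(rng.normal(size=5), train_s, train_c, k=10)
        assert np.all(out >= 0.2) and np.all(out <= 0.6)

    def test_fewer_points_than_k_uses_all(self):
        out = knn_calibrate(0.0, [1.0, 2.0], [0.2, 0.4], k=30)
        assert out == pytest.approx(0.3)


class TestLinearCorrection:
    def test_already_matching_moments_unchanged(self, rng):
        p = rng.uniform(0.2, 0.8, size=50)
        out = linear_correction(p, p.mean(), p.std())
        assert np.allclose(out, p)

    def test_affine_closed_form(self):
        out = linear_correction([0.0, 1.0], 0.5, 0.25)
        assert np.allclose(out, [0.25, 0.75])

    def test_corrected_mean_exact_before_clipping(self, rng):
        p = rng.uniform(0.3, 0.7, size=80)
        out = linear_correction(p, 0.5, 0.1)
        assert out.mean() == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_collapses_to_target_mean(self):
        out = linear_correction(np.full(10, 0.4), 0.6, 0.1)
        assert np.allclose(out, 0.6)


def _monotone_table(rng, n=200, n_noise=7):
    z = rng.integers(1, 37, size=n)
    y = np.asarray(level_to_cellularity(z))
    X = rng.normal(size=(n, 1 + n_noise))
    X[:, 0] = np.sqrt(y)
    return X, y


#: Small-sample settings used by the in-test fits (tree leaves down to a
#: few samples, the desk-scale RankNet rate); mirrors the package's
#: desk-scale experiment profile.
_SMALL = {
    "huber_gbdt": {"min_child_samples": 2},
    "ranknet_gbdt": {"learning_rate": 0.2},
    "svr": None,
    "rank_svm": None,
}


class TestTrainEstimator:
    @pytest.mark.parametrize("kind", ["huber_gbdt", "ranknet_gbdt", "svr", "rank_svm"])
    def test_noiseless_monotone_signal_recovered(self, kind, rng):
        """y a noiseless monotone function of one feature: held-out
        ranking is essentially perfect (ties induced by clipping and
        KNN-calibration plateaus cost a few thousandths of tau)."""
        z = rng.integers(1, 37, size=300)
        y = np.asarray(level_to_cellularity(z))
        X = np.sqrt(y)[:, None]
        est = train_estimator(kind, X[:220], y[:220], params=_SMALL[kind], seed=0)
        tau = kendall_tau_b(est.predict(X[220:]), y[220:])
        assert tau > 0.95

    @pytest.mark.parametrize("kind", ["huber_gbdt", "svr"])
    def test_same_seed_identical_predictions(self, kind, rng):
        X, y = _monotone_table(rng, n=120)
        a = train_estimator(kind, X, y, seed=3).predict(X)
        b = train_estimator(kind, X, y, seed=3).predict(X)
        assert np.array_equal(a, b)

    def test_predictions_clipped_to_unit_interval(self, rng):
        X, y = _monotone_table(rng, n=120)
        est = train_estimator("huber_gbdt", X, y, seed=0)
        p = est.predict(rng.normal(size=(50, 8)) * 10)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_zero_cellularity_training_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.linspace(0, 1, 30)
        with pytest.raises(InvalidTrainingSetError):
            train_estimator("huber_gbdt", X, y)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            train_estimator("ridge", rng.normal(size=(10, 2)), np.full(10, 0.5))

    def test_ranking_kinds_store_calibration(self, rng):
        X, y = _monotone_table(rng, n=120)
        est = train_estimator("rank_svm", X, y, seed=0)
        assert est.calibration is not None
        est2 = train_estimator("svr", X, y, seed=0)
        assert est2.calibration is None

    def test_svr_linear_kernel_matches_least_squares_on_noiseless_data(self, rng):
        """With a linear kernel, eps = 0 and strong C, SVR on noiseless
        linear data reproduces the least-squares fit."""
        X = rng.normal(size=(80, 3))
        w = np.array([0.05, 0.03, -0.04])
        y = 0.4 + X @ w
        est = train_estimator(
            "svr", X, np.clip(y, 0.01, 1.0),
            params={"kernel": "linear", "C": 1e4, "gamma": "scale"},
            seed=0, apply_correction=False,
        )
        coef = np.linalg.lstsq(
            np.column_stack([np.ones(80), X]), y, rcond=None
        )[0]
        ols_pred = coef[0] + X @ coef[1:]
        assert np.abs(est.raw_scores(X) - ols_pred).max() < 1e-3
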