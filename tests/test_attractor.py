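import numpy as np
import pytest

from cspam import (
    DegenerateAttractorError,
    InvalidInputError,
    am_weights,
    incremental_subset_selection,
    normalized_mutual_information,
    rank_features,
)


class TestNMI:
    def test_perfect_dependence(self, rng):
        x = rng.standard_normal(200)
        assert normalized_mutual_information(x, x) == pytest.approx(1.0)

    def test_independent_samples_near_zero(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert normalized_mutual_information(x, y) < 0.05

    def test_uniform_joint_is_zero(self):
        # joint histogram uniform over 2x2 bins -> MI = 0 by hand
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert normalized_mutual_information(x, y, n_bins=2) == 0.0

    def test_symmetry(self, rng):
        x, y = rng.standard_normal(500), rng.standard_normal(500)
        y = y + 0.5 * x
        assert normalized_mutual_information(x, y) == pytest.approx(
            normalized_mutual_information(y, x)
        )

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            x = rng.standard_normal(100)
            y = 0.7 * x + 0.3 * rng.standard_normal(100)
            v = normalized_mutual_information(x, y)
            assert 0.0 <= v <= 1.0

    def test_constant_input_returns_zero(self, rng):
        assert normalized_mutual_information(
            np.ones(50), rng.standard_normal(50)
        ) == 0.0

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            normalized_mutual_information(np.arange(5), np.arange(6))


class TestAMWeights:
    def test_single_feature_converges_to_one(self, rng):
        G = rng.standard_normal((1, 100))
        r = am_weights(G, seed=0)
        assert r.converged and r.iterations_used <= 2
        assert r.weights[0] == pytest.approx(1.0)

    def test_anticorrelated_feature_gated_to_zero(self, rng):
        latent = rng.standard_normal(300)
        G = np.vstack([
            latent + 0.1 * rng.standard_normal(300),
            latent + 0.1 * rng.standard_normal(300),
            -latent + 0.1 * rng.standard_normal(300),
        ])
        r = am_weights(G, seed=1)
        assert r.converged
        assert r.weights[2] == 0.0
        assert r.weights[0] > 0.2 and r.weights[1] > 0.2

    def test_alpha_zero_gives_unit_weights(self, rng):
        latent = rng.standard_normal(200)
        G = np.vstack([latent + 0.2 * rng.standard_normal(200) for _ in range(4)])
        r = am_weights(G, alpha=0.0, seed=2)
        np.testing.assert_allclose(r.weights, 1.0)

    def test_weights_bounded_unit_interval(self, rng):
        G = rng.standard_normal((10, 150))
        try:
            r = am_weights(G, seed=3)
        except DegenerateAttractorError:
            return  # pure-noise matrices may legitimately collapse
        assert np.all(r.weights >= 0) and np.all(r.weights <= 1)

    def test_seeded_determinism(self, rng):
        G = rng.standard_normal((8, 120))
        G[:4] += rng.standard_normal(120)  # shared structure
        r1 = am_weights(G, seed=42)
        r2 = am_weights(G, seed=42)
        np.testing.assert_array_equal(r1.weights, r2.weights)
        np.testing.assert_array_equal(r1.order, r2.order)

    def test_degenerate_attractor_raises(self):
        # feature anti-correlated with any positive mix of itself is
        # impossible; force collapse with two exactly opposed features and an
        # equal init, whose metagene is constant zero
        G = np.vstack([np.linspace(-1, 1, 50), -np.linspace(-1, 1, 50)])
        with pytest.raises(DegenerateAttractorError):
            am_weights(G, init="equal")

    def test_invalid_params_rejected(self, rng):
        G = rng.standard_normal((3, 50))
        with pytest.raises(InvalidInputError):
            am_weights(G, alpha=-1.0)
        with pytest.raises(InvalidInputError):
            am_weights(G, tol=0.0)

    def test_planted_relevance_ranks_high(self):
        """Noisy copies of one latent signal outrank independent noise."""
        top8 = 0
        for seed in range(10):
            r2 = np.random.default_rng(1000 + seed)
            latent = r2.standard_normal(200)
            G = np.vstack(
                [latent + 0.5 * r2.standard_normal(200) for _ in range(4)]
                + [r2.standard_normal(200) for _ in range(36)]
            )
            rk = am_weights(G, seed=seed)
            ranks = [int(np.flatnonzero(rk.order == j)[0]) for j in range(4)]
            top8 += sum(r < 8 for r in ranks)
        assert top8 / 40 > 0.7   # most planted features land in the top 8


class TestRankFeatures:
    def test_simple_sort(self):
        np.testing.assert_array_equal(rank_features([0.2, 0.9, 0.5]), [1, 2, 0])

    def test_all_equal_gives_identity(self):
        np.testing.assert_array_equal(rank_features(np.ones(5)), np.arange(5))

    def test_matches_reference_sort(self, rng):
        w = rng.random(40).round(2)   # rounded to force some ties
        order = rank_features(w)
        # independent oracle: stable lexicographic sort on (-w, index)
        oracle = sorted(range(40), key=lambda i: (-w[i], i))
        np.testing.assert_array_equal(order, oracle)

    def test_rejects_negative_or_nonfinite(self):
        with pytest.raises(InvalidInputError):
            rank_features([0.1, -0.2])
        with pytest.raises(InvalidInputError):
            rank_features([np.nan, 0.2])


class _ScriptedClassifier:
    """Training-accuracy stub keyed on how many features it sees."""

    def __init__(self, scores_by_k):
        self.scores_by_k = scores_by_k

    def fit(self, X, y):
        self._k = X.shape[1]
        self._y = np.asarray(y)
        return self

    def predict(self, X):
        # reproduce exactly scores_by_k[k-1] training accuracy
        target = self.scores_by_k[self._k - 1]
        n = len(self._y)
        n_correct = int(round(target * n))
        pred = self._y.copy()
        flip = np.arange(n_correct, n)
        pred[flip] = np.where(self._y[flip] == "a", "b", "a")
        return pred


class TestSubsetSelection:
    def _run(self, scores):
        p = len(scores)
        G = np.random.default_rng(0).standard_normal((p, 80))
        y = np.array(["a", "b"] * 40)
        return incremental_subset_selection(
            G, y, classifier_factory=lambda: _ScriptedClassifier(scores)
        )

    def test_flat_perfect_scores_pick_k1(self):
        assert self._run([1.0] * 10).k == 1

    def test_minimal_k_at_tied_maximum(self):
        sel = self._run([0.5, 0.7, 0.7, 0.6, 0.5])
        assert sel.k == 2 and sel.score == pytest.approx(0.7)

    def test_all_forty_candidates_evaluated(self):
        sel = self._run(list(np.arange(41, 81) / 80))   # strictly increasing
        assert len(sel.scores_by_k) == 40
        assert sel.k == 40

    def test_indices_are_prefix_of_order(self, rng):
        G = rng.standard_normal((6, 40))
        y = np.array(["a"] * 20 + ["b"] * 20)
        G[0] += np.where(y == "a", 2.0, -2.0)   # feature 0 separates
        order = np.array([0, 3, 1, 5, 2, 4])
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        sel = incremental_subset_selection(
            G, y, classifier_factory=LinearDiscriminantAnalysis, order=order
        )
        np.testing.assert_array_equal(sel.indices, order[: sel.k])

    def test_no_smaller_k_beats_selected(self):
        sel = self._run([0.3, 0.8, 0.6, 0.8, 0.9, 0.9])
        better_earlier = [
            k for k in range(1, sel.k) if sel.scores_by_k[k - 1] > sel.score
        ]
        assert sel.k == 5 and not better_earlier
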