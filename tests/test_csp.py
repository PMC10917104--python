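import numpy as np
import pytest
from scipy import linalg

from cspam import (
    InvalidInputError,
    csp_features,
    filterbank_features,
    fit_csp_pair,
    mean_class_covariance,
    normalized_trial_covariance,
    pattern_recovery_score,
)
from cspam.synthetic import GroundTruth


def random_psd(rng, n):
    A = rng.standard_normal((n, n))
    S = A @ A.T + 0.1 * np.eye(n)
    return S / np.trace(S)


class TestTrialCovariance:
    def test_identity_trial(self):
        S = normalized_trial_covariance(np.eye(2))
        np.testing.assert_allclose(S, np.eye(2) / 2)

    def test_hadamard_trial(self):
        # E E^T = 2I, trace 4 -> I/2
        S = normalized_trial_covariance(np.array([[1.0, 1.0], [1.0, -1.0]]))
        np.testing.assert_allclose(S, np.eye(2) / 2)

    def test_unit_trace_and_psd(self, rng):
        for _ in range(20):
            E = rng.standard_normal((6, 50))
            S = normalized_trial_covariance(E)
            assert np.isclose(np.trace(S), 1.0)
            assert np.allclose(S, S.T)
            assert linalg.eigvalsh(S).min() > -1e-12

    def test_all_zero_trial_rejected(self):
        with pytest.raises(InvalidInputError):
            normalized_trial_covariance(np.zeros((3, 10)))


class TestMeanCovariance:
    def test_single_and_pairwise_mean(self, rng):
        S1, S2 = random_psd(rng, 4), random_psd(rng, 4)
        np.testing.assert_allclose(mean_class_covariance([S1]), S1)
        np.testing.assert_allclose(mean_class_covariance([S1, S2]), (S1 + S2) / 2)

    def test_white_noise_converges_to_isotropic(self, rng):
        covs = [
            normalized_trial_covariance(rng.standard_normal((4, 100)))
            for _ in range(2000)
        ]
        mean = mean_class_covariance(covs)
        assert np.abs(mean - np.eye(4) / 4).max() < 0.02

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidInputError):
            mean_class_covariance([])


class TestFitCSP:
    def test_identical_classes_give_half_eigenvalues(self, rng):
        S = random_psd(rng, 8)
        model = fit_csp_pair(S, S, n_pairs=2)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-10)

    def test_diagonal_two_channel_case(self):
        Sx = np.diag([0.8, 0.2])
        Sy = np.diag([0.2, 0.8])
        model = fit_csp_pair(Sx, Sy, n_pairs=1)
        np.testing.assert_allclose(model.eigenvalues, [0.8, 0.2], atol=1e-12)
        # filters along coordinate axes up to scale
        for row in model.filters:
            assert np.min(np.abs(row)) < 1e-10 * np.max(np.abs(row))

    def test_matches_generalized_eig_oracle(self, rng):
        """Whitening path agrees with scipy's generalized eigensolver."""
        for _ in range(20):
            Sx, Sy = random_psd(rng, 8), random_psd(rng, 8)
            model = fit_csp_pair(Sx, Sy, n_pairs=4)
            lam, vec = linalg.eigh(Sx, Sx + Sy)
            lam_desc = lam[::-1]
            np.testing.assert_allclose(model.eigenvalues, lam_desc, atol=1e-8)
            # filters parallel to oracle eigenvectors (sign/scale free)
            for i, w in enumerate(model.filters):
                v = vec[:, ::-1][:, i]
                cos = np.abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
                assert cos > 1 - 1e-8

    def test_whitening_contract_and_complementarity(self, rng):
        Sx, Sy = random_psd(rng, 8), random_psd(rng, 8)
        model = fit_csp_pair(Sx, Sy, n_pairs=4)
        W = model.filters
        np.testing.assert_allclose(W @ (Sx + Sy) @ W.T, np.eye(8), atol=1e-8)
        # eigenvalue under the other class is 1 - lambda
        lam_y = np.einsum("ij,jk,ik->i", W, Sy, W)
        np.testing.assert_allclose(lam_y, 1 - model.eigenvalues, atol=1e-8)

    def test_eigenvalues_descending_and_sign_convention(self, rng):
        Sx, Sy = random_psd(rng, 10), random_psd(rng, 10)
        model = fit_csp_pair(Sx, Sy, n_pairs=3)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        for row in model.filters:
            assert row[np.argmax(np.abs(row))] > 0

    def test_patterns_invert_filters(self, rng):
        Sx, Sy = random_psd(rng, 6), random_psd(rng, 6)
        model = fit_csp_pair(Sx, Sy, n_pairs=3)   # full decomposition
        np.testing.assert_allclose(
            model.filters @ model.patterns.T, np.eye(6), atol=1e-8
        )

    def test_too_many_pairs_rejected(self, rng):
        S = random_psd(rng, 4)
        with pytest.raises(InvalidInputError):
            fit_csp_pair(S, S, n_pairs=3)

    def test_rank_deficient_composite_regularized(self, rng, caplog):
        v = rng.standard_normal(6)
        S_low = np.outer(v, v)
        S_low /= np.trace(S_low)
        model = fit_csp_pair(S_low, S_low, n_pairs=1)
        assert np.all(np.isfinite(model.filters))


class TestFeatures:
    def _model(self, rng, n_ch=8, n_pairs=4):
        return fit_csp_pair(random_psd(rng, n_ch), random_psd(rng, n_ch),
                            n_pairs=n_pairs)

    def test_length_and_logsumexp_normalization(self, rng):
        model = self._model(rng)
        f = csp_features(rng.standard_normal((8, 100)), model)
        assert f.shape == (8,)
        assert np.isclose(np.exp(f).sum(), 1.0)

    def test_signal_along_first_pattern_maximizes_first_feature(self, rng):
        model = self._model(rng)
        s = rng.standard_normal(200)
        E = np.outer(model.patterns[0], s)      # pure component-1 signal
        f = csp_features(E + 1e-9 * rng.standard_normal((8, 200)), model)
        assert np.argmax(f) == 0

    def test_scale_invariance(self, rng):
        model = self._model(rng)
        E = rng.standard_normal((8, 100))
        np.testing.assert_allclose(
            csp_features(E, model), csp_features(17.3 * E, model), atol=1e-10
        )

    def test_channel_mismatch_rejected(self, rng):
        model = self._model(rng)
        with pytest.raises(InvalidInputError):
            csp_features(rng.standard_normal((5, 100)), model)

    def test_filterbank_concatenation(self, rng):
        models = [self._model(rng) for _ in range(5)]
        trial = [rng.standard_normal((8, 64)) for _ in range(5)]
        f = filterbank_features(trial, models)
        assert f.shape == (40,)
        # reordering bands permutes feature blocks identically
        perm = [3, 1, 4, 0, 2]
        fp = filterbank_features([trial[i] for i in perm],
                                 [models[i] for i in perm])
        np.testing.assert_allclose(fp, np.concatenate(
            [f[8 * i : 8 * (i + 1)] for i in perm]))

    def test_degenerate_single_band_single_pair(self, rng):
        model = fit_csp_pair(random_psd(rng, 4), random_psd(rng, 4), n_pairs=1)
        f = filterbank_features([rng.standard_normal((4, 64))], [model])
        assert f.shape == (2,)

    def test_band_count_mismatch_rejected(self, rng):
        models = [self._model(rng) for _ in range(2)]
        with pytest.raises(InvalidInputError):
            filterbank_features([rng.standard_normal((8, 64))], models)


class TestPatternRecovery:
    def _truth(self, pattern):
        p = np.asarray(pattern, dtype=float)
        p = p / np.linalg.norm(p)
        return GroundTruth(
            patterns=p[None, None, :], source_bands=((8.0, 12.0),),
            class_labels=("a",), trial_amplitudes=np.zeros((1, 1)),
            noise_mixing=np.eye(p.size), snr=1.0, seed=0,
        )

    def test_self_and_scaled_recovery(self, rng):
        p = rng.standard_normal(10)
        truth = self._truth(p)
        assert np.isclose(pattern_recovery_score(p, truth, "a"), 1.0)
        assert np.isclose(pattern_recovery_score(-2 * p, truth, "a"), 1.0)

    def test_matches_hand_rolled_correlation(self, rng):
        p = rng.standard_normal(10)
        q = rng.standard_normal(10)
        truth = self._truth(p)
        pc, qc = (p / np.linalg.norm(p)) - np.mean(p / np.linalg.norm(p)), q - q.mean()
        hand = abs(float(np.dot(pc, qc) / np.sqrt(np.sum(pc**2) * np.sum(qc**2))))
        assert np.isclose(pattern_recovery_score(q, truth, "a"), hand)

    def test_zero_variance_rejected(self):
        truth = self._truth(np.arange(1, 6, dtype=float))
        with pytest.raises(InvalidInputError):
            pattern_recovery_score(np.ones(5), truth, "a")
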