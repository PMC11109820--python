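import itertools

import numpy as np
import pytest

from parcelmeg import (
    Parcellation,
    aec,
    band_envelope,
    make_parcellation,
    summarize,
    symmetric_orthogonalize,
)
from parcelmeg.connectivity import ConnectivityMatrix


def gram_schmidt(X):
    """Sequential orthogonalization oracle (order-dependent)."""
    Y = X.astype(float).copy()
    for i in range(1, len(Y)):
        for j in range(i):
            Y[i] -= (Y[i] @ Y[j]) / (Y[j] @ Y[j]) * Y[j]
    return Y


class TestSymmetricOrthogonalize:
    def test_orthogonal_input_is_fixed_point(self):
        # zero-mean, mutually orthogonal rows: integer-cycle sinusoids
        t = np.arange(2000)
        X = np.vstack([
            2.0 * np.sin(2 * np.pi * 5 * t / 2000),
            0.7 * np.cos(2 * np.pi * 11 * t / 2000),
            1.3 * np.sin(2 * np.pi * 17 * t / 2000),
        ])
        O = symmetric_orthogonalize(X)
        assert np.linalg.norm(O - X) < 1e-8

    def test_output_exactly_uncorrelated(self, rng):
        X = rng.standard_normal((5, 10000))
        X[1] = 0.5 * X[0] + np.sqrt(0.75) * X[1]
        O = symmetric_orthogonalize(X)
        C = np.corrcoef(O)
        np.fill_diagonal(C, 0.0)
        assert np.abs(C).max() < 1e-6

    def test_fixed_point_of_itself(self, rng):
        X = rng.standard_normal((4, 5000))
        O = symmetric_orthogonalize(X)
        O2 = symmetric_orthogonalize(O)
        assert np.linalg.norm(O2 - O) / np.linalg.norm(O) < 1e-6

    def test_closer_than_every_gram_schmidt_ordering(self, rng):
        """Symmetric treatment beats sequential orthogonalization under all
        5! = 120 parcel orderings (brute-force oracle)."""
        X = rng.standard_normal((5, 10000))
        X[2] = 0.6 * X[0] + 0.8 * X[2]
        X -= X.mean(axis=1, keepdims=True)
        d_sym = np.linalg.norm(symmetric_orthogonalize(X) - X)
        for perm in itertools.permutations(range(5)):
            Xp = X[list(perm)]
            d_gs = np.linalg.norm(gram_schmidt(Xp) - Xp)
            assert d_sym <= d_gs + 1e-9

    def test_rank_deficient_rejected(self, rng):
        X = rng.standard_normal((3, 1000))
        X[2] = X[0] + X[1]
        with pytest.raises(ValueError, match="rank"):
            symmetric_orthogonalize(X)

    def test_more_parcels_than_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            symmetric_orthogonalize(rng.standard_normal((10, 5)))


class TestBandEnvelope:
    def test_am_sinusoid_envelope_recovered(self):
        fs = 250.0
        t = np.arange(int(60 * fs)) / fs
        a = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)  # slow positive envelope
        x = a * np.sin(2 * np.pi * 10 * t)
        env = band_envelope(x[None, :], (7.0, 13.0), fs)[0]
        interior = slice(int(2 * fs), int(-2 * fs))
        rel_err = np.abs(env[interior] - a[interior]) / a[interior]
        assert rel_err.max() < 0.05

    def test_zero_input_zero_envelope(self):
        env = band_envelope(np.zeros((2, 1000)), (7.0, 13.0), 250.0)
        assert np.allclose(env, 0.0)

    def test_envelope_nonnegative(self, rng):
        env = band_envelope(rng.standard_normal((3, 5000)), (13.0, 30.0), 250.0)
        assert (env >= 0).all()

    def test_band_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            band_envelope(rng.standard_normal((2, 1000)), (52.0, 80.0), 100.0)


class TestAec:
    def test_identical_envelopes_correlate_fully(self, rng):
        e = np.abs(rng.standard_normal(5000)) + 0.1
        m = aec(np.vstack([e, e])).aec
        assert m[0, 1] == pytest.approx(1.0)

    def test_independent_envelopes_near_zero(self, rng):
        fs = 250.0
        x = rng.standard_normal((4, int(300 * fs)))
        env = band_envelope(x, (7.0, 13.0), fs)
        m = aec(env, edge_trim_s=1.0, fs=fs).aec
        off = m[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_scale_invariance(self, rng):
        env = np.abs(rng.standard_normal((3, 4000))) + 0.1
        m1 = aec(env).aec
        m2 = aec(env * np.array([[2.0], [5.0], [0.3]])).aec
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(m1[off], m2[off], atol=1e-12)

    def test_constant_envelope_rejected(self):
        env = np.vstack([np.ones(1000), np.abs(np.sin(np.arange(1000) / 7)) + 0.1])
        with pytest.raises(ValueError, match="constant"):
            aec(env)


def _conn(matrix, band="alpha"):
    m = matrix.astype(float).copy()
    np.fill_diagonal(m, np.nan)
    return ConnectivityMatrix(band=band, aec=m)


class TestSummarize:
    def test_uniform_matrix(self, parc4):
        m = np.full((4, 4), 0.3)
        s = summarize(_conn(m), parc4)
        assert np.allclose(s.global_mean, 0.3)
        assert np.allclose(s.intra_mean, 0.3)
        assert np.allclose(s.inter_mean, 0.3)
        assert np.allclose(s.lateralization, 0.0)

    def test_block_structure_hand_computed(self, parc4):
        """0.6 within hemispheres, 0.2 across: intra 0.6, inter 0.2,
        global (0.6 + 2 * 0.2) / 3 = 1/3 for every parcel."""
        hemi = np.array(parc4.hemisphere)
        same = hemi[:, None] == hemi[None, :]
        m = np.where(same, 0.6, 0.2)
        s = summarize(_conn(m), parc4)
        assert np.allclose(s.intra_mean, 0.6)
        assert np.allclose(s.inter_mean, 0.2)
        assert np.allclose(s.global_mean, (0.6 + 2 * 0.2) / 3)

    def test_global_is_weighted_mean_of_intra_inter(self, rng):
        parc = make_parcellation(4)
        m = rng.uniform(-0.5, 0.8, size=(8, 8))
        m = (m + m.T) / 2
        s = summarize(_conn(m), parc)
        n_intra, n_inter = 3, 4
        expected = (n_intra * s.intra_mean + n_inter * s.inter_mean) / 7
        np.testing.assert_allclose(s.global_mean, expected, atol=1e-12)

    def test_parcel_permutation_equivariance(self, rng):
        parc = make_parcellation(3)
        m = rng.uniform(0, 0.9, size=(6, 6))
        m = (m + m.T) / 2
        s = summarize(_conn(m), parc)
        perm = [3, 1, 5, 0, 2, 4]
        labels = tuple(parc.labels[i] for i in perm)
        hemis = tuple(parc.hemisphere[i] for i in perm)
        parc_p = Parcellation(labels=labels, hemisphere=hemis)
        s_p = summarize(_conn(m[np.ix_(perm, perm)]), parc_p)
        inv = np.argsort(perm)
        np.testing.assert_allclose(s_p.global_mean[inv][np.argsort(inv)],
                                   s_p.global_mean)  # sanity on indexing
        np.testing.assert_allclose(np.array(s.global_mean)[perm], s_p.global_mean)
        np.testing.assert_allclose(np.array(s.intra_mean)[perm], s_p.intra_mean)

    def test_single_parcel_hemisphere_rejected(self):
        parc = Parcellation(labels=("a", "b", "c"),
                            hemisphere=("left", "right", "right"))
        m = np.full((3, 3), 0.2)
        with pytest.raises(ValueError, match="hemisphere"):
            summarize(_conn(m), parc)

    def test_dimension_mismatch_rejected(self, parc4):
        with pytest.raises(ValueError, match="match"):
            summarize(_conn(np.full((6, 6), 0.1)), parc4)
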