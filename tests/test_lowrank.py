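"""PCT / sparse PCT decompositions and avatar assembly."""

from itertools import combinations

import numpy as np
import pytest

import thermomics as tm
from thermomics.errors import ValidationError
from thermomics.lowrank import BasisSet

from conftest import wrap_heat_matrix


def brute_force_svd(X):
    """Independent SVD oracle via eigendecomposition of X^T X."""
    w, V = np.linalg.eigh(X.T @ X)
    idx = np.argsort(w)[::-1]
    s = np.sqrt(np.maximum(w[idx], 0.0))
    U = X @ V[:, idx] / np.where(s > 0, s, 1.0)
    return U, s


def brute_force_sparse_support(X, card):
    """Exhaustive support enumeration maximizing v^T (X X^T) v, |v|_0 = card."""
    S = X @ X.T
    p = S.shape[0]
    return max(combinations(range(p), card),
               key=lambda c: np.linalg.eigvalsh(S[np.ix_(c, c)])[-1])


class TestPct:
    def test_rank_one_matrix(self):
        u = np.array([3.0, 0.0, 4.0, 0.0, 0.0, 0.0])
        v = np.array([1.0, -2.0, 2.0])
        hm = wrap_heat_matrix(np.outer(u, v))
        bs = tm.pct(hm, 3)
        assert bs.singular_values[0] == pytest.approx(5.0 * 3.0)
        assert np.abs(bs.singular_values[1:]).max() < 1e-10
        b1 = bs.bases[0].ravel()
        assert np.abs(b1 - u / 5.0).max() < 1e-10  # sign convention: +0.8 at idx 2
        recon = bs.singular_values[0] * np.outer(b1, bs.coefficients[:, 0])
        assert np.abs(recon - hm.X).max() < 1e-10

    def test_matches_brute_force_svd_oracle(self, rng):
        for _ in range(5):
            X = rng.standard_normal((6, 4))
            hm = wrap_heat_matrix(X)
            bs = tm.pct(hm, 4)
            U, s = brute_force_svd(X)
            assert np.abs(bs.singular_values - s).max() < 1e-10
            for i in range(4):
                u = bs.bases[i].ravel()
                assert min(np.abs(u - U[:, i]).max(),
                           np.abs(u + U[:, i]).max()) < 1e-10

    def test_phantom_yields_three_bases(self):
        seqs, _ = tm.generate_cohort(0, 1, seed=2)
        hm = tm.build_heat_matrix(seqs[0])
        bs = tm.pct(hm, 3)
        assert len(bs.bases) == 3
        assert all(b.shape == hm.roi_shape for b in bs.bases)
        assert np.all(np.diff(bs.singular_values) <= 1e-12)

    def test_orthonormal_bases(self, tiny_hm):
        bs = tm.pct(tiny_hm, 4)
        U = np.stack([b.ravel() for b in bs.bases], axis=1)
        assert np.abs(U.T @ U - np.eye(4)).max() < 1e-8

    def test_total_variance_equals_frobenius(self, tiny_hm):
        bs = tm.pct(tiny_hm, 4)
        assert np.sum(bs.singular_values**2) == pytest.approx(
            np.linalg.norm(tiny_hm.X, "fro") ** 2, rel=1e-8)

    def test_reconstruction_error_non_increasing_in_k(self, rng):
        X = rng.standard_normal((8, 5))
        hm = wrap_heat_matrix(X)
        errs = []
        for k in range(1, 6):
            bs = tm.pct(hm, k)
            U = np.stack([b.ravel() for b in bs.bases], axis=1)
            approx = U @ np.diag(bs.singular_values) @ bs.coefficients.T
            errs.append(np.linalg.norm(X - approx, "fro"))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-10  # zero at full rank

    def test_k_out_of_range(self, tiny_hm):
        with pytest.raises(ValidationError):
            tm.pct(tiny_hm, 0)
        with pytest.raises(ValidationError):
            tm.pct(tiny_hm, 5)


class TestSparsePct:
    def test_zero_penalties_equal_pct(self, tiny_hm):
        ref = tm.pct(tiny_hm, 3)
        bs = tm.sparse_pct(tiny_hm, 3, lambda1=0.0, lambda2=0.0)
        for i in range(3):
            u, v = bs.bases[i].ravel(), ref.bases[i].ravel()
            assert min(np.abs(u - v).max(), np.abs(u + v).max()) < 1e-8
        assert np.abs(bs.singular_values - ref.singular_values).max() < 1e-8

    def test_planted_support_matches_enumeration_oracle(self, rng):
        """Cardinality cap 2 recovers the exhaustive-search support (p <= 10)."""
        for trial in range(3):
            p, n = 8, 6
            X = 0.1 * rng.standard_normal((p, n))
            v = np.zeros(p)
            i, j = (2, 5) if trial == 0 else rng.choice(p, 2, replace=False)
            v[i], v[j] = 0.8, -0.6
            X += np.outer(v, 3.0 * rng.standard_normal(n))
            hm = wrap_heat_matrix(X)
            bs = tm.sparse_pct(hm, 1, card=2)
            support = set(np.flatnonzero(np.abs(bs.bases[0].ravel()) > 1e-12))
            assert support == set(brute_force_sparse_support(X, 2))

    def test_nnz_non_increasing_in_lambda1(self, rng):
        X = rng.standard_normal((8, 6))
        hm = wrap_heat_matrix(X)
        nnz = [int((np.abs(tm.sparse_pct(hm, 1, lambda1=lam).bases[0]) > 1e-12).sum())
               for lam in (0.0, 0.02, 0.05, 0.1, 0.2, 0.3)]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_unit_norm_bases(self, tiny_hm):
        bs = tm.sparse_pct(tiny_hm, 3, lambda1=0.1)
        for b in bs.bases:
            assert np.linalg.norm(b.ravel()) == pytest.approx(1.0, abs=1e-10)

    def test_noisy_planted_support_recovered(self, rng):
        """Sparse signal + Gaussian noise at high SNR: support recovered."""
        p, n = 10, 8
        v = np.zeros(p)
        v[[1, 4, 7]] = np.array([0.6, -0.6, 0.52])
        v /= np.linalg.norm(v)
        X = np.outer(v, 5.0 * rng.standard_normal(n)) + 0.05 * rng.standard_normal((p, n))
        bs = tm.sparse_pct(wrap_heat_matrix(X), 1, card=3)
        assert set(np.flatnonzero(np.abs(bs.bases[0].ravel()) > 1e-12)) == {1, 4, 7}

    def test_deterministic(self, tiny_hm):
        a = tm.sparse_pct(tiny_hm, 2, lambda1=0.05)
        b = tm.sparse_pct(tiny_hm, 2, lambda1=0.05)
        for x, y in zip(a.bases, b.bases):
            assert np.array_equal(x, y)

    def test_negative_penalty_rejected(self, tiny_hm):
        with pytest.raises(ValidationError):
            tm.sparse_pct(tiny_hm, 2, lambda1=-0.1)


class TestVarianceFraction:
    def make_bs(self, svals):
        svals = np.asarray(svals, dtype=float)
        k = svals.size
        return BasisSet(bases=[np.zeros((2, 2))] * k, singular_values=svals,
                        coefficients=np.zeros((k, k)), k=k, method="pct",
                        roi_shape=(2, 2))

    def test_worked_example(self):
        # squared: 4,1,1 -> cumulative 4/6 < 0.8 <= 5/6
        assert tm.variance_fraction(self.make_bs([2.0, 1.0, 1.0]), 0.8) == 2

    def test_threshold_one_needs_all(self):
        assert tm.variance_fraction(self.make_bs([2.0, 1.0, 1.0]), 1.0) == 3

    def test_single_component(self):
        assert tm.variance_fraction(self.make_bs([3.0]), 0.5) == 1

    def test_monotone_in_threshold(self):
        bs = self.make_bs([3.0, 2.0, 1.0, 0.5])
        counts = [tm.variance_fraction(bs, t) for t in (0.2, 0.5, 0.8, 0.99, 1.0)]
        assert counts == sorted(counts)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            tm.variance_fraction(self.make_bs([]), 0.8)


class TestMakeAvatar:
    def from_bases(self, bases):
        k = len(bases)
        return BasisSet(bases=list(bases), singular_values=np.ones(k),
                        coefficients=np.zeros((k, k)), k=k, method="pct",
                        roi_shape=bases[0].shape)

    def test_output_geometry(self, rng):
        bs = self.from_bases([rng.standard_normal((20, 30)) for _ in range(3)])
        av = tm.make_avatar(bs)
        assert av.image.shape == (224, 224, 3)
        assert av.image.min() >= 0.0 and av.image.max() <= 1.0

    def test_constant_basis_maps_to_zero_channel(self, rng):
        bs = self.from_bases([np.full((10, 10), 7.0),
                              rng.standard_normal((10, 10)),
                              rng.standard_normal((10, 10))])
        av = tm.make_avatar(bs, side=10)
        assert np.abs(av.image[:, :, 0]).max() == 0.0
        assert av.image[:, :, 1].max() > 0

    def test_channel_order_round_trip(self, rng):
        """Bases already spanning [0,1]: channels recoverable in order."""
        b1 = np.zeros((10, 10)); b1[0, 0] = 1.0
        b2 = np.zeros((10, 10)); b2[5, 5] = 1.0
        b3 = np.zeros((10, 10)); b3[9, 9] = 1.0
        av = tm.make_avatar(self.from_bases([b1, b2, b3]), side=10)
        assert np.array_equal(av.image[:, :, 0], b1)
        assert np.array_equal(av.image[:, :, 1], b2)
        assert np.array_equal(av.image[:, :, 2], b3)

    def test_center_crop_is_square(self, rng):
        bs = self.from_bases([rng.standard_normal((16, 24)) for _ in range(3)])
        av = tm.make_avatar(bs, side=8)
        assert av.image.shape == (8, 8, 3)

    def test_fewer_than_three_bases_rejected(self, rng):
        bs = self.from_bases([rng.standard_normal((8, 8)) for _ in range(2)])
        with pytest.raises(ValidationError, match="3 bases"):
            tm.make_avatar(bs)
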