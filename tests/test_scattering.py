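import numpy as np
import pytest

from facescatter import (
    MomentConfig,
    affinity_matrix,
    build_wavelets,
    eigendecompose,
    feature_length,
    first_moments,
    laplacian,
    scatter,
    second_moments,
    zeroth_moments,
)
from facescatter.spectral import SpectralBasis
from facescatter.synth import random_rotation
from facescatter import LandmarkSet

from conftest import random_landmarks


def full_basis(rng, C):
    return eigendecompose(laplacian(affinity_matrix(random_landmarks(rng, C))), k=C)


def dense_wavelet_matrices(L, J):
    """Independent construction: heat kernels from a full eigensolve,
    wavelets as explicit C x C matrix differences."""
    vals, vecs = np.linalg.eigh(L)

    def H(t):
        return (vecs * np.exp(-vals * t)) @ vecs.T

    Ws = [np.eye(L.shape[0]) - H(1.0)]
    for j in range(1, J + 1):
        Ws.append(H(2.0 ** (j - 1)) - H(2.0**j))
    return Ws, H(2.0**J)


def loop_moments(mat, Q):
    C, n = mat.shape
    out = np.zeros((n, len(Q)))
    for ch in range(n):
        for qi, q in enumerate(Q):
            out[ch, qi] = np.mean([abs(mat[c, ch]) ** q for c in range(C)])
    return out


class TestWaveletBank:
    def test_j0_structure(self, rng):
        b = full_basis(rng, 6)
        bank = build_wavelets(b, J=0)
        f = rng.normal(size=6)
        H1 = (b.vectors * np.exp(-b.eigenvalues)) @ b.vectors.T
        np.testing.assert_allclose(bank.apply(0, f), f - H1 @ f, atol=1e-10)
        np.testing.assert_allclose(bank.apply_lowpass(f), H1 @ f, atol=1e-10)

    @pytest.mark.parametrize("J", [0, 1, 2, 3])
    def test_telescoping_identity_complete_basis(self, rng, J):
        b = full_basis(rng, 8)
        bank = build_wavelets(b, J=J)
        f = rng.normal(size=(8, 3))
        total = sum(bank.apply(j, f) for j in range(J + 1)) + bank.apply_lowpass(f)
        np.testing.assert_allclose(total, f, atol=1e-10)

    def test_constant_passes_only_through_lowpass(self, rng):
        b = full_basis(rng, 7)
        bank = build_wavelets(b, J=2)
        c = 2.5 * np.ones(7)
        for j in range(3):
            assert np.abs(bank.apply(j, c)).max() < 1e-9
        np.testing.assert_allclose(bank.apply_lowpass(c), c, atol=1e-9)

    def test_negative_J_rejected(self, rng):
        with pytest.raises(ValueError):
            build_wavelets(full_basis(rng, 5), J=-1)


class TestZerothMoments:
    def test_constant_channel(self):
        mat = np.full((5, 1), 3.0)
        m = zeroth_moments(mat, MomentConfig(Q=(1.0,)))
        assert m[0, 0] == pytest.approx(3.0)

    def test_arithmetic_example(self):
        mat = np.array([[3.0], [4.0]])
        m = zeroth_moments(mat, MomentConfig(Q=(2.0,)))
        assert m[0, 0] == pytest.approx(12.5)

    def test_matches_loop_oracle(self, rng):
        mat = rng.normal(size=(6, 4))
        Q = (0.5, 1.0, 2.0)
        np.testing.assert_allclose(
            zeroth_moments(mat, MomentConfig(Q=Q)), loop_moments(mat, Q), rtol=1e-12
        )


class TestFirstMoments:
    def test_constant_field_annihilated(self, rng):
        b = full_basis(rng, 6)
        bank = build_wavelets(b, J=2)
        mat = np.ones((6, 3)) * 4.0
        first, _ = first_moments(mat, bank, MomentConfig())
        assert np.abs(first).max() < 1e-9

    def test_eigenvector_fixed_point(self, rng):
        b = full_basis(rng, 6)
        bank = build_wavelets(b, J=0)
        phi1, lam1 = b.vectors[:, 1], b.eigenvalues[1]
        first, _ = first_moments(phi1[:, None], bank, MomentConfig(Q=(1.0,)))
        expected = (1 - np.exp(-lam1)) * np.mean(np.abs(phi1))
        assert first[0, 0, 0] == pytest.approx(expected, rel=1e-10)

    def test_matches_dense_operator_oracle(self, rng):
        lm = random_landmarks(rng, 9)
        L = laplacian(affinity_matrix(lm))
        b = eigendecompose(L, k=9)
        bank = build_wavelets(b, J=2)
        mat = rng.normal(size=(9, 5))
        Q = (0.5, 1.0, 2.0)
        first, low = first_moments(mat, bank, MomentConfig(Q=Q))
        Ws, A = dense_wavelet_matrices(L, J=2)
        for j in range(3):
            np.testing.assert_allclose(
                first[:, j, :], loop_moments(Ws[j] @ mat, Q), atol=1e-10
            )
        np.testing.assert_allclose(low, loop_moments(A @ mat, Q), atol=1e-10)


class TestSecondMoments:
    def test_no_pairs_at_J0(self, rng):
        bank = build_wavelets(full_basis(rng, 5), J=0)
        out, pairs = second_moments(rng.normal(size=(5, 2)), bank)
        assert out.shape == (2, 0, 3) and pairs == []

    def test_constant_field_zero(self, rng):
        bank = build_wavelets(full_basis(rng, 5), J=2)
        out, _ = second_moments(np.ones((5, 2)), bank)
        assert np.abs(out).max() < 1e-12

    def test_matches_dense_nested_oracle(self, rng):
        lm = random_landmarks(rng, 8)
        L = laplacian(affinity_matrix(lm))
        bank = build_wavelets(eigendecompose(L, k=8), J=2)
        mat = rng.normal(size=(8, 4))
        Q = (0.5, 1.0, 2.0)
        out, pairs = second_moments(mat, bank, MomentConfig(Q=Q))
        Ws, _ = dense_wavelet_matrices(L, J=2)
        for pi, (j, jp) in enumerate(pairs):
            expected = loop_moments(Ws[jp] @ np.abs(Ws[j] @ mat), Q)
            np.testing.assert_allclose(out[:, pi, :], expected, atol=1e-10)

    def test_pairs_are_strictly_increasing(self, rng):
        bank = build_wavelets(full_basis(rng, 5), J=3)
        _, pairs = second_moments(rng.normal(size=(5, 1)), bank)
        assert pairs == [(j, jp) for j in range(4) for jp in range(j + 1, 4)]
        assert len(pairs) == 3 * 4 // 2


class TestScatter:
    def test_flat_length_default_settings(self, rng):
        # C=22, M^3=1000 channels, J=0, |Q|=3, low-pass on -> 9000
        b = full_basis(rng, 22)
        feats = scatter(rng.random(size=(22, 1000)), b, J=0)
        assert feats.flat.shape == (9000,)
        assert feature_length(1000, 0, MomentConfig()) == 9000

    def test_flat_length_formula_with_second_order(self, rng):
        b = full_basis(rng, 6)
        cfg = MomentConfig(Q=(1.0, 2.0))
        feats = scatter(rng.random(size=(6, 10)), b, J=2, config=cfg)
        # 1 zeroth + 3 first + 1 lowpass + 3 second orders, 2 exponents
        assert feats.flat.shape == (10 * 2 * (1 + 3 + 1 + 3),)
        assert len(feats.flat) == feature_length(10, 2, cfg)

    def test_landmark_permutation_invariance(self, rng):
        lm = random_landmarks(rng, 8)
        mat = rng.random(size=(8, 5))
        perm = rng.permutation(8)
        b1 = eigendecompose(laplacian(affinity_matrix(lm)), k=6)
        b2 = eigendecompose(
            laplacian(affinity_matrix(LandmarkSet(lm.coords[perm]))), k=6
        )
        f1 = scatter(mat, b1, J=1)
        f2 = scatter(mat[perm], b2, J=1)
        np.testing.assert_allclose(f1.flat, f2.flat, atol=1e-10)

    def test_rigid_motion_invariance_fixed_field(self, rng):
        lm = random_landmarks(rng, 8)
        mat = rng.random(size=(8, 5))
        R = random_rotation(rng, 180.0)
        moved = LandmarkSet(lm.coords @ R.T + [10.0, 0.0, -4.0])
        b1 = eigendecompose(laplacian(affinity_matrix(lm)), k=6)
        b2 = eigendecompose(laplacian(affinity_matrix(moved)), k=6)
        np.testing.assert_allclose(
            scatter(mat, b1, J=1).flat, scatter(mat, b2, J=1).flat, atol=1e-9
        )

    def test_field_scaling_homogeneity(self, rng):
        b = full_basis(rng, 6)
        mat = rng.random(size=(6, 4))
        s = 3.0
        f1 = scatter(mat, b, J=1)
        f2 = scatter(s * mat, b, J=1)
        # every q-moment scales as s^q: check per q block exactly
        for qi, q in enumerate(f1.Q):
            np.testing.assert_allclose(
                f2.zeroth[:, qi], s**q * f1.zeroth[:, qi], rtol=1e-12
            )
            np.testing.assert_allclose(
                f2.first[:, :, qi], s**q * f1.first[:, :, qi], rtol=1e-10, atol=1e-300
            )

    def test_sign_flip_invariance(self, rng):
        b = full_basis(rng, 7)
        flipped = SpectralBasis(
            eigenvalues=b.eigenvalues.copy(),
            vectors=b.vectors * np.where(rng.random(7) < 0.5, -1.0, 1.0),
            C=b.C,
        )
        mat = rng.random(size=(7, 3))
        np.testing.assert_allclose(
            scatter(mat, b, J=2).flat, scatter(mat, flipped, J=2).flat, atol=1e-10
        )

    def test_all_features_finite_nonnegative(self, rng):
        b = full_basis(rng, 6)
        flat = scatter(rng.normal(size=(6, 10)), b, J=2).flat
        assert np.all(np.isfinite(flat)) and np.all(flat >= 0)

    def test_mismatched_C_rejected(self, rng):
        b = full_basis(rng, 6)
        with pytest.raises(ValueError):
            scatter(rng.random(size=(7, 3)), b)
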