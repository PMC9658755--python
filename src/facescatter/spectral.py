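"""Landmark-graph Laplacian, its eigenbasis, and heat-semigroup filters.

The C landmarks form a small weighted graph with Gaussian affinities
``W_ij = exp(-||p_i - p_j||^2 / eps)`` (zero diagonal). The scaled graph
Laplacian

    L = (1 / (eps * C)) (D - W),    D = diag(row sums of W),

is the discrete stand-in for the negative Laplace-Beltrami operator of the
coarse face surface the landmarks skeletonize. Because W depends only on
pairwise distances, L — and hence everything built from it — is invariant
under rigid motions of the landmark set.

Heat filters act spectrally: ``H_t f = sum_k exp(-lambda_k t) <f, phi_k> phi_k``
over the retained eigenpairs, which gives the exact semigroup property
H_t H_s = H_{t+s} by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io import LandmarkSet

__all__ = [
    "LandmarkGraph",
    "SpectralBasis",
    "affinity_matrix",
    "laplacian",
    "eigendecompose",
    "spectral_coefficients",
    "heat_apply",
    "heat_multipliers",
]


@dataclass
class LandmarkGraph:
    W: np.ndarray  # (C, C) symmetric, zero diagonal, entries in [0, 1]
    epsilon: float

    @property
    def C(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)


@dataclass
class SpectralBasis:
    """Truncated eigenbasis of the landmark Laplacian.

    eigenvalues are sorted ascending; eigenvectors are orthonormal columns
    of ``vectors`` with a fixed sign convention (largest-|entry| component
    positive) for reproducibility — all downstream operators use phi phi^T
    projections and are sign-invariant regardless.
    """

    eigenvalues: np.ndarray  # (k,)
    vectors: np.ndarray  # (C, k)
    C: int

    @property
    def k(self) -> int:
        return len(self.eigenvalues)


def affinity_matrix(landmarks: LandmarkSet | np.ndarray, epsilon: float | None = None) -> LandmarkGraph:
    """Gaussian affinity graph over the landmarks.

    ``epsilon=None`` uses the standard diffusion-maps auto rule: the mean of
    all squared pairwise landmark distances (diagonal excluded).
    """
    coords = landmarks.coords if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks, float)
    C = len(coords)
    if C < 3:
        raise ValueError("need at least 3 landmarks")
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if epsilon is None:
        off = d2[~np.eye(C, dtype=bool)]
        epsilon = float(off.mean())
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    W = np.exp(-d2 / epsilon)
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)  # exact symmetry against rounding
    return LandmarkGraph(W=W, epsilon=float(epsilon))


def laplacian(graph: LandmarkGraph) -> np.ndarray:
    """Scaled graph Laplacian L = (D - W) / (eps * C); symmetric PSD with
    the constant vector in its null space."""
    D = np.diag(graph.degrees)
    L = (D - graph.W) / (graph.epsilon * graph.C)
    return 0.5 * (L + L.T)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


def eigendecompose(L: np.ndarray, k: int = 6, which: str = "smallest_magnitude") -> SpectralBasis:
    """Dense eigendecomposition of L, keeping k eigenpairs by |lambda|.

    ``which`` selects the smallest- or largest-magnitude eigenvalues; the
    retained pairs are returned ascending by eigenvalue. Dense solve is
    always used (C <= 83 in practice).
    """
    L = np.asarray(L, dtype=float)
    C = L.shape[0]
    if not 1 <= k <= C:
        raise ValueError(f"k must be in [1, {C}], got {k}")
    vals, vecs = scipy.linalg.eigh(L)
    order = np.argsort(np.abs(vals), kind="stable")
    if which == "smallest_magnitude":
        keep = order[:k]
    elif which == "largest_magnitude":
        keep = order[-k:]
    else:
        raise ValueError(f"unknown eigenvalue selection {which!r}")
    keep = keep[np.argsort(vals[keep], kind="stable")]
    return SpectralBasis(eigenvalues=vals[keep], vectors=_fix_signs(vecs[:, keep]), C=C)


def spectral_coefficients(signal: np.ndarray, basis: SpectralBasis) -> np.ndarray:
    """Inner products <f, phi_k> of a length-C signal (or C x n channels)."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != basis.C:
        raise ValueError(f"signal length {signal.shape[0]} != C {basis.C}")
    return basis.vectors.T @ signal


def heat_multipliers(basis: SpectralBasis, t: float) -> np.ndarray:
    if t < 0:
        raise ValueError("diffusion time t must be >= 0")
    return np.exp(-basis.eigenvalues * t)


def heat_apply(basis: SpectralBasis, t: float, signal: np.ndarray) -> np.ndarray:
    """Apply the heat filter H_t spectrally to a length-C signal or (C, n)
    multi-channel array. With a truncated basis the output lies in the span
    of the retained eigenvectors."""
    coeffs = spectral_coefficients(signal, basis)
    m = heat_multipliers(basis, t)
    return basis.vectors @ (m[:, None] * coeffs if coeffs.ndim == 2 else m * coeffs)
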