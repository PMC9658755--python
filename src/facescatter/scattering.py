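"""Diffusion-wavelet bank and scattering moments on the landmark graph.

Wavelets are differences of heat kernels at dyadic diffusion times,

    W_0 = Id - H_1,   W_j = H_{2^(j-1)} - H_{2^j}  (1 <= j <= J),
    A_J = H_{2^J}  (global low-pass),

realized as spectral multiplier operators on the retained eigenbasis; on the
complete basis the bank telescopes exactly to the identity. Scattering
moments integrate modulus nonlinearities of the filtered density field over
the landmark set with uniform weights 1/C:

    zeroth   S|rho|^q         = (1/C) sum_c |rho_c|^q
    first    S rho[j, q]      = (1/C) sum_c |(W_j rho)_c|^q
    second   S rho[j, j', q]  = (1/C) sum_c |(W_j' |W_j rho|)_c|^q,  j' > j.

The modulus is applied before the power (mandatory for fractional q). Each
lattice node of the density descriptor is one channel; the C landmark blocks
are the manifold samples of that channel. Moments are invariant to landmark
permutations, to rigid motions of the landmark set, and to eigenvector sign
flips, and scale as s^q when the field is scaled by s.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .density import DensityField
from .spectral import SpectralBasis, heat_multipliers

__all__ = [
    "WaveletBank",
    "MomentConfig",
    "ScatteringFeatures",
    "build_wavelets",
    "zeroth_moments",
    "first_moments",
    "second_moments",
    "scatter",
]


@dataclass
class WaveletBank:
    """Dyadic diffusion wavelets {W_j}_{j=0..J} plus the low-pass A_J.

    Stored as spectral multipliers over the basis eigenvalues; ``operator(j)``
    materializes the dense C x C matrix phi diag(m) phi^T.
    """

    J: int
    basis: SpectralBasis
    multipliers: np.ndarray  # (J+1, k) wavelet multipliers
    lowpass: np.ndarray  # (k,) A_J multipliers

    def apply(self, j: int, signal: np.ndarray) -> np.ndarray:
        return self._apply_mult(self.multipliers[j], signal)

    def apply_lowpass(self, signal: np.ndarray) -> np.ndarray:
        return self._apply_mult(self.lowpass, signal)

    def _apply_mult(self, m: np.ndarray, signal: np.ndarray) -> np.ndarray:
        signal = np.asarray(signal, dtype=float)
        if signal.shape[0] != self.basis.C:
            raise ValueError(f"signal has {signal.shape[0]} rows, expected C={self.basis.C}")
        coeffs = self.basis.vectors.T @ signal
        scaled = m[:, None] * coeffs if coeffs.ndim == 2 else m * coeffs
        return self.basis.vectors @ scaled

    def operator(self, j: int) -> np.ndarray:
        V = self.basis.vectors
        return V @ np.diag(self.multipliers[j]) @ V.T

    def lowpass_operator(self) -> np.ndarray:
        V = self.basis.vectors
        return V @ np.diag(self.lowpass) @ V.T


@dataclass
class MomentConfig:
    """Which moments to emit: exponents Q, second order, low-pass moments."""

    Q: tuple[float, ...] = (0.5, 1.0, 2.0)
    include_second_order: bool = True
    include_lowpass_moments: bool = True

    def __post_init__(self) -> None:
        self.Q = tuple(float(q) for q in self.Q)
        if not self.Q:
            raise ValueError("Q must be non-empty")
        if any(q <= 0 for q in self.Q):
            raise ValueError("all moment exponents q must be positive")


@dataclass
class ScatteringFeatures:
    """Per-channel scattering moments plus the deterministic flat vector.

    Flat order: zeroth by (channel, q); first by (channel, j, q); low-pass
    moments by (channel, q) if enabled; second by (channel, j, j', q) for
    j' > j.
    """

    zeroth: np.ndarray  # (n_channels, |Q|)
    first: np.ndarray  # (n_channels, J+1, |Q|)
    lowpass: np.ndarray | None  # (n_channels, |Q|) or None
    second: np.ndarray | None  # (n_channels, n_pairs, |Q|) or None
    J: int
    Q: tuple[float, ...]
    fingerprint: str = ""
    pair_index: list[tuple[int, int]] = field(default_factory=list)

    @property
    def flat(self) -> np.ndarray:
        parts = [self.zeroth.reshape(self.zeroth.shape[0], -1)]
        parts.append(self.first.reshape(self.first.shape[0], -1))
        if self.lowpass is not None:
            parts.append(self.lowpass)
        if self.second is not None and self.second.size:
            parts.append(self.second.reshape(self.second.shape[0], -1))
        return np.concatenate([p.ravel() for p in parts])


def build_wavelets(basis: SpectralBasis, J: int = 0) -> WaveletBank:
    """Construct the dyadic bank; J=0 gives {W_0 = Id - H_1, A_0 = H_1}."""
    if J < 0:
        raise ValueError("J must be >= 0")
    mults = np.empty((J + 1, basis.k))
    mults[0] = 1.0 - heat_multipliers(basis, 1.0)
    for j in range(1, J + 1):
        mults[j] = heat_multipliers(basis, 2.0 ** (j - 1)) - heat_multipliers(basis, 2.0**j)
    lowpass = heat_multipliers(basis, 2.0**J)
    return WaveletBank(J=J, basis=basis, multipliers=mults, lowpass=lowpass)


def _as_field_matrix(field_like) -> np.ndarray:
    if isinstance(field_like, DensityField):
        return field_like.as_matrix()
    return np.atleast_2d(np.asarray(field_like, dtype=float).T).T  # (C,) -> (C, 1)


def _moment(values: np.ndarray, Q: tuple[float, ...]) -> np.ndarray:
    """(1/C) sum_c |values|^q for each q; values is (C, n) -> (n, |Q|)."""
    a = np.abs(values)
    return np.stack([a**q for q in Q], axis=-1).mean(axis=0)


def zeroth_moments(field_like, config: MomentConfig | None = None) -> np.ndarray:
    """q-th power averages of the raw field over landmarks: (n_channels, |Q|)."""
    config = config or MomentConfig()
    return _moment(_as_field_matrix(field_like), config.Q)


def first_moments(field_like, bank: WaveletBank, config: MomentConfig | None = None):
    """Wavelet-band moments (n_channels, J+1, |Q|), plus low-pass moments
    (n_channels, |Q|) when enabled (else None)."""
    config = config or MomentConfig()
    mat = _as_field_matrix(field_like)
    out = np.stack([_moment(bank.apply(j, mat), config.Q) for j in range(bank.J + 1)], axis=1)
    low = _moment(bank.apply_lowpass(mat), config.Q) if config.include_lowpass_moments else None
    return out, low

def second_moments(field_like, bank: WaveletBank, config: MomentConfig | None = None):
    """Iterated-band moments for j' > j: (n_channels, J(J+1)/2, |Q|).

    At J=0 there are no valid (j, j') pairs and an empty array is returned.
    """
    config = config or MomentConfig()
    mat = _as_field_matrix(field_like)
    pairs = [(j, jp) for j in range(bank.J + 1) for jp in range(j + 1, bank.J + 1)]
    if not pairs:
        return np.empty((mat.shape[1], 0, len(config.Q))), []
    out = np.stack(
        [_moment(bank.apply(jp, np.abs(bank.apply(j, mat))), config.Q) for j, jp in pairs],
        axis=1,
    )
    return out, pairs


def _fingerprint(J: int, config: MomentConfig, basis: SpectralBasis, extra: dict | None) -> str:
    payload = {
        "J": J,
        "Q": list(config.Q),
        "second": config.include_second_order,
        "lowpass": config.include_lowpass_moments,
        "k": basis.k,
    }
    if extra:
        payload.update(extra)
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def scatter(
    field_like,
    basis: SpectralBasis,
    J: int = 0,
    config: MomentConfig | None = None,
    fingerprint_extra: dict | None = None,
) -> ScatteringFeatures:
    """Full scattering representation of one sample.

    ``field_like`` is the (C, n_channels) density field (lattice nodes are
    channels). Flat length is
    n_channels * |Q| * (1 + (J+1) + lowpass + J(J+1)/2).
    """
    config = config or MomentConfig()
    mat = _as_field_matrix(field_like)
    if mat.shape[0] != basis.C:
        raise ValueError(f"field has {mat.shape[0]} rows but basis C={basis.C}")
    bank = build_wavelets(basis, J)
    zeroth = zeroth_moments(mat, config)
    first, low = first_moments(mat, bank, config)
    if config.include_second_order:
        second, pairs = second_moments(mat, bank, config)
    else:
        second, pairs = None, []
    return ScatteringFeatures(
        zeroth=zeroth,
        first=first,
        lowpass=low,
        second=second,
        J=J,
        Q=config.Q,
        fingerprint=_fingerprint(J, config, basis, fingerprint_extra),
        pair_index=pairs,
    )


def feature_length(n_channels: int, J: int, config: MomentConfig) -> int:
    """Closed-form flat-vector length for given settings."""
    n_orders = 1 + (J + 1) + (1 if config.include_lowpass_moments else 0)
    if config.include_second_order:
        n_orders += J * (J + 1) // 2
    return n_channels * len(config.Q) * n_orders
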