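"""Build the landmark-graph Laplacian, its heat filters and diffusion wavelets.

The 22 landmarks form a small Gaussian-affinity graph; its scaled Laplacian
approximates the face surface's Laplace-Beltrami operator. Heat filters
H_t = e^{-tL} act spectrally; wavelets are differences of heat filters at
dyadic times and telescope back to the identity.
"""

import numpy as np

from facescatter import (
    FaceSpec,
    affinity_matrix,
    build_wavelets,
    eigendecompose,
    generate_face,
    heat_apply,
    laplacian,
)

_, landmarks, _ = generate_face(FaceSpec(subject_seed=3, sample_seed=5, class_id=0))
graph = affinity_matrix(landmarks)  # auto epsilon: mean squared pairwise distance
L = laplacian(graph)
basis = eigendecompose(L, k=22)  # complete basis for the identities below

print(f"epsilon = {graph.epsilon:.1f} mm^2")
print(f"smallest eigenvalues: {np.round(basis.eigenvalues[:4], 6)}")  # lambda_0 = 0

f = np.random.default_rng(0).normal(size=22)
h = heat_apply(basis, 2.0, heat_apply(basis, 3.0, f))
print("semigroup H_2 H_3 = H_5:", np.allclose(h, heat_apply(basis, 5.0, f), atol=1e-10))

bank = build_wavelets(basis, J=2)
total = sum(bank.apply(j, f) for j in range(3)) + bank.apply_lowpass(f)
print("wavelet frame telescopes to identity:", np.allclose(total, f, atol=1e-10))
# lambda_0 = 0 with the constant eigenvector: diffusion preserves means, and
# all wavelet bands annihilate constant signals.
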