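# Methods

This note documents the model, the defaults and why they are what they are,
what the synthetic data does and does not emulate, and the numerical
choices that make results reproducible.

## Pipeline model

A sample is a pair (point cloud `x`, landmark set `{p_c}` with C ≥ 3). The
representation is built in three stages.

**Density descriptor.** For each landmark, the K nearest cloud points
(Euclidean; exact ties broken by original point index) are evaluated on a
regular M×M×M lattice centered at the landmark via a Gaussian sum
`ρ_c(μ) = Σ_n exp(−‖μ−r_n‖²/2σ²)` with no tail truncation and no kernel
normalization constant; each block is then normalized to unit sum (an
all-zero block stays zero). The lattice is axis-aligned with the global
frame and translated to the landmark: this makes the descriptor exactly
invariant to joint translations and exactly permutation-invariant, at the
price of rotation sensitivity, which is deliberate — isometry handling is
delegated to the spectral stage, and the per-sample pose nuisance is part
of what the classifier must absorb.

**Landmark spectrum.** Gaussian affinities `W_ij = exp(−‖p_i−p_j‖²/ε)` with
zero diagonal; ε defaults to the mean squared pairwise distance (the usual
diffusion-maps estimator, keeping entries well scaled for any head size).
The Laplacian is `L = (D−W)/(εC)`, symmetric PSD with the constant vector
in its null space; rigid motions leave it invariant because only pairwise
distances enter. A dense eigensolve (C ≤ 83, no iterative solver needed)
retains k eigenpairs selected by smallest |λ| (largest optionally).

**Scattering moments.** Heat multipliers `e^{−λt}` define
`W_0 = Id − H_1`, `W_j = H_{2^{j−1}} − H_{2^j}`, `A_J = H_{2^J}`; on the
complete basis the bank telescopes to the identity. Each lattice node is a
channel; the C landmark values of a channel form the graph signal.
Integration over the landmark "manifold" is a uniform 1/C average — the
only quadrature that keeps permutation invariance exact (degree-weighted
quadrature would also be defensible but breaks nothing-up-my-sleeve
symmetry of the moments). The modulus is applied before the power (required
for q = 0.5), second order is restricted to j′ > j, and the low-pass
moments of `A_J ρ` are included by default since the low-pass band is part
of the transform output. Flat feature order: zeroth by (channel, q), first
by (channel, j, q), low-pass by (channel, q), second by (channel, j, j′, q).

Defaults J=0, Q=(0.5, 1, 2), k=6, smallest-magnitude spectrum — the
settings the tuning experiments favored. At J=0 there are no second-order
terms, so a C=22, M=10 sample yields 1000 × 3 × 3 = 9000 features.

Note that the 1/(εC) Laplacian scaling makes the eigenvalues very small in
physical units (ε is a squared length, ~10⁴ mm² for a head-sized landmark
set). The dyadic diffusion times then sit far below 1/λ, so the wavelet
bands respond weakly relative to the low-pass and zeroth moments. The
scaling is kept as stated because it only rescales the spectrum; the
classifier standardizes features per dimension, which removes the scale
asymmetry between bands.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| K (neighbors) | 512 | – | sets the patch scale (~3.5 cm at 8k-point scans). Small patches (K≈64, ~1.3 cm) are more local but make the descriptor fragile to landmark placement error of a few mm; the robustness the method claims requires the patch to dwarf the annotation noise. 512 keeps the patch local to one expressive region while a 3 mm landmark shift moves the lattice by <10% of its extent. |
| M (lattice) | 10 | – | the standard local frame resolution; cost grows as M³. |
| half-width | auto | mm | median over landmarks of the K-th-neighbor distance, per sample — scale-adaptive so the lattice always covers its patch. |
| σ (kernel) | α × spacing, α=1 | mm | smoothing proportional to lattice spacing keeps the descriptor resolution-matched at any scale. |
| ε (affinity) | mean squared pairwise distance | mm² | diffusion-maps default. |
| k (eigenpairs) | 6 | – | coarse geometry only; the landmark graph is a skeleton, not a mesh. |
| J, Q | 0, (0.5, 1, 2) | – | tuned defaults; J=0 keeps only the finest band plus low-pass. |
| splits | 70/20/10 × 10 repeats | subjects | subject-disjoint; largest-remainder rounding on subject counts. |
| SVM grid | C ∈ {0.1,1,10,100}, γ ∈ {0.1,1,10}/d | – | spans under- to over-regularized; ties go to the smallest penalty, then smallest γ. |
| sparse head | 64 atoms, T=3, λ init 0.1 | – | dictionary size of the order of the training-set size under the 14-subject protocol; T=3 unrolled ISTA steps suffice for a re-encoding layer. |
| SGD | lr 0.001, batch 32, wd 0.001, momentum 0.9, 60 epochs | – | standard momentum-SGD recipe for this scale; Adam is available but not better here. |

## Sparse-coding head

The head computes T unrolled proximal-gradient (ISTA) steps
`z ← soft(z + η Dᵀ(x − Dz), η λ)` from z = 0, with η = 1/σ_max(D)²
recomputed per update by warm-started power iteration, followed by a linear
softmax layer; D and the threshold λ are learned end-to-end with exact
reverse-mode gradients through the unrolled iterations (η is treated as a
constant of each forward pass, the standard practice for unrolled solvers).
The threshold is scaled by the step size so the layer is a true proximal
descent on `½‖x − Dz‖² + λ‖z‖₁`: run long enough it converges to that
lasso solution, which is what the correctness tests check against an
independent coordinate-descent solver.

Model selection keeps the epoch with the best validation accuracy, breaking
ties by lower validation cross-entropy. The tie-break matters: with ~20
validation samples, accuracy saturates within a few epochs, and selecting
the first saturated epoch returns an undertrained model; among saturated
epochs the lower-loss one has larger margins and measurably better
held-out-subject accuracy.

## Synthetic data: what it emulates, what it does not

The generator mimics the statistical structure of frontal expression scan
corpora: per-subject base shape (jittered ellipsoid semi-axes plus smooth
random radial bumps — the identity confound that makes subject-disjoint
splitting meaningful), class-specific signed radial Gaussian deformations
(amplitude 10 mm, angular width 0.18 rad ≈ 1.5 cm — the magnitude and
locality of prototypical expressions) at eight expressive landmarks,
isotropic point jitter (0.5 mm), frontal oversampling, and a per-sample
rigid pose (≤10°, ≤20 mm). Landmarks are pushed through the same
deformations, as manual annotations on expressive regions are.

It does **not** emulate: realistic facial topology (noses, eye sockets),
occlusions (hair, glasses, hands), scanner artifacts (holes, spikes),
correlated non-Gaussian noise, or expression intensity variation. Passing
the recovery experiment therefore shows the pipeline separates localized
surface deformations across subject and pose nuisance — not that it
reaches any particular accuracy on real faces.

Seeding: subject shape uses `SeedSequence([seed, subject])`; each sample
uses `SeedSequence([seed, subject, class, rep])`. Every output is a pure
function of these integers.

The landmark-noise experiment follows the stated rule literally: the noise
*variance* equals the fraction (default 0.10) of the mean pairwise landmark
distance, applied per coordinate. This is dimensionally odd (a variance set
from a length) but is implemented as stated, with `as_std=True` available
for the standard-deviation reading. Noised test features are scored by the
models trained on clean features, through the clean-fitted standardizer.

## Numerical choices

- KNN by brute-force lexsort on (distance, index): deterministic tie-break,
  exact, and fast at these sizes; no KD-tree, whose tie order is unspecified.
- Eigenvector signs fixed (largest-|entry| component positive); all
  downstream operators use φφᵀ projections and are provably sign-invariant,
  the convention only stabilizes serialized artifacts.
- W and L are explicitly symmetrized after construction to remove rounding
  asymmetry before `eigh`.
- Standardization guards constant feature dimensions (std < 1e-12 pass
  through) and records a fingerprint of the rows it was fitted on, so
  leakage of validation/test rows into the transform is detectable.
- Splits re-draw (up to 100 times) when a class is absent from a training
  split, which can only happen when a class is carried by very few subjects.
- Degenerate inputs: empty neighbor sets give zero blocks; normalization
  leaves all-zero blocks untouched; fraction-zero landmark noise is an
  exact identity.

## Experiment sizes

The shipped study uses 14 subjects × 7 expressions × 1 sample (98 scans of
8000 points each), 10 split repeats, and a 10,000-draw noise calibration —
sizes chosen so the whole study runs end-to-end in minutes on one CPU while
leaving every protocol element (subject-disjointness, repeated splits,
validation-based selection, same-model robustness scoring) intact. Larger
corpora only shrink the error bars; nothing in the implementation depends
on these sizes.

## Known limitations

- The descriptor is rotation-sensitive by design; very large pose ranges
  (≫10°) would need either pose normalization upstream or the optional
  surface-aligned lattice (not implemented).
- ISTA unrolled to T=3 is a feature transform, not a converged sparse
  coder; its lasso-optimality is only exercised at large T in tests.
- The landmark graph uses a single global ε; strongly non-uniform landmark
  layouts (dense around the mouth, sparse elsewhere) may deserve local
  scaling.
- With J=0 the second-order scattering path is empty; deeper banks are
  implemented and tested but not exercised by the default study.
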