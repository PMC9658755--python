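# facescatter

Geometric scattering on landmark graphs for 3D facial-expression
recognition from raw point clouds.

## The problem

A 3D face scan is an unordered set of ~8k–50k points. Expressions are
*local* deformations (mouth corners, brows) riding on much larger nuisance
variation: who the subject is, how the head is posed, how densely the
scanner sampled the surface, and how precisely the anatomical landmarks
were annotated. A useful representation must keep the local deformation
signal while being stable to everything else — permutation of point order,
rigid motion, sampling density, and landmark placement error.

`facescatter` implements a pipeline that does this with no meshes and no
texture, consuming only point coordinates and C manually annotated
landmarks (C = 22 or 83 in the common corpora):

1. **Local density descriptor.** Around each landmark `p_c`, the K nearest
   points are smoothed onto a regular M×M×M lattice by a Gaussian kernel:
   `ρ_c(μ) = Σ_n exp(−‖μ − r_n‖² / 2σ²)`, each block normalized to sum 1.
   This is an unnormalized KDE on a local grid — permutation-invariant,
   fixed-length, resolution-independent.
2. **Landmark-graph spectrum.** The landmarks form a small graph with
   Gaussian affinities `W_ij = exp(−‖p_i − p_j‖²/ε)`; the scaled Laplacian
   `L = (D − W)/(εC)` is a discrete Laplace–Beltrami surrogate whose
   spectrum depends only on pairwise distances, hence is isometry-invariant.
3. **Manifold scattering transform.** Heat filters `H_t = e^{−tL}` build
   dyadic diffusion wavelets `W_0 = Id − H_1`, `W_j = H_{2^{j−1}} − H_{2^j}`,
   low-pass `A_J = H_{2^J}`. Treating each lattice node as a channel over
   the C landmarks, the features are scattering moments
   `Sρ^q = (1/C) Σ_c |ρ_c|^q`, `Sρ[j,q] = (1/C) Σ_c |(W_j ρ)_c|^q`, and
   iterated second-order moments for `j′ > j`.
4. **Classifier heads** under a subject-disjoint repeated-split protocol
   (70/20/10 over subjects, 10 repeats, mean test accuracy): an RBF-SVM
   with validation-grid search, and a sparse-coding head — T unrolled ISTA
   iterations over a learnable dictionary feeding a fully-connected softmax
   layer, trained by momentum SGD.

Licensed scan corpora cannot ship with a library, so the package includes a
first-class synthetic generator: ellipsoidal "heads" with per-subject bumps,
class-specific local radial deformations at designated expressive landmarks,
point jitter, non-uniform frontal sampling and random pose, with landmarks
riding the deformed surface.

## Worked example

```python
from facescatter import FaceSpec, generate_face, extract_sample
from facescatter.pipeline import PipelineConfig

cloud, landmarks, label = generate_face(
    FaceSpec(subject_seed=3, sample_seed=5, class_id=2))
features = extract_sample(cloud, landmarks, PipelineConfig())
print(len(features))   # 9000
```

With the default settings (M=10 lattice → 1000 channels, Q=(0.5,1,2), J=0
with low-pass moments) each sample becomes a 9000-dimensional vector.
Running the narrative scripts in `examples/` prints, among others:

```
$ python examples/03_spectral_wavelets.py
epsilon = 10484.1 mm^2
smallest eigenvalues: [0.0e+00 2.3e-05 2.8e-05 3.1e-05]
semigroup H_2 H_3 = H_5: True
wavelet frame telescopes to identity: True

$ python examples/05_classification_protocol.py
features: 48 samples x 9000 dims
svm: mean held-out-subject accuracy 1.000 (chance 0.250), per repeat [1.0, 1.0, 1.0]
nn: mean held-out-subject accuracy 1.000 (chance 0.250), per repeat [1.0, 1.0, 1.0]
```

The eigenvalue list shows the Laplacian's null mode (λ₀ = 0, the constant
vector) and the near-zero low-frequency modes that parameterize the coarse
face geometry; accuracies above chance on held-out subjects show the
features carry expression identity across subjects the classifier never saw.

A command-line driver mirrors the library:

```bash
facescatter synth --subjects 14 --classes 7 --seed 1 --out data/
facescatter extract --manifest data/manifest.csv --out feats.h5
facescatter train --features feats.h5 --head nn --out report.json
facescatter perturb --manifest data/manifest.csv --fraction 0.10 --out robustness.json
```

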