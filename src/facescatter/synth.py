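"""Synthetic landmarked "expressive face" point clouds.

Real 3D expression corpora (frontal scans of many subjects performing a
small set of prototypical expressions) are licensed and cannot ship with a
library, so this module generates point clouds with the same statistical
structure the method assumes:

* a per-subject base shape — an ellipsoid with jittered semi-axes plus a few
  smooth subject-specific radial Gaussian bumps (the identity confound);
* a class-specific expression — signed radial Gaussian displacement fields
  centered at a designated subset of "expressive" landmarks, with widths
  small enough that the deformation is genuinely local;
* nuisance factors — isotropic point jitter, non-uniform sampling density
  (frontal oversampling, as a frontal scanner produces), and a per-sample
  random rigid motion (head pose);
* landmarks that ride the deformed surface, as manual annotations on
  expressive regions do.

Every output is a pure function of its seeds. Per-sample seeds are derived
from the dataset seed with ``numpy.random.SeedSequence([seed, subject,
class, rep])`` (the documented counter scheme); subject-level shape uses
``SeedSequence([seed, subject])`` so all samples of one subject share a base
shape — the subject-disjoint split protocol is only meaningful if they do.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .io import (
    DatasetManifest,
    LandmarkSet,
    ManifestRecord,
    PointCloud,
    write_landmarks,
    write_manifest,
    write_pointcloud,
)

__all__ = [
    "FaceSpec",
    "DatasetSpec",
    "landmark_template",
    "expression_patterns",
    "generate_face",
    "generate_dataset",
    "perturb_landmarks",
    "perturb_cloud",
    "random_rotation",
]

# Default class vocabulary mirrors the seven-expression protocol
# (anger, disgust, fear, happiness, sadness, surprise, neutral).
CLASS_NAMES_7 = ("AN", "DI", "FE", "HA", "SA", "SU", "NE")
CLASS_NAMES_6 = ("AN", "DI", "FE", "HA", "SA", "SU")


def landmark_template(C: int = 22) -> np.ndarray:
    """C fixed unit directions on the frontal hemisphere (z > 0).

    A deterministic Fibonacci lattice mapped to the front of the head, so
    landmark layouts are comparable across subjects (like a manual
    annotation protocol).
    """
    if C < 4:
        raise ValueError("landmark template needs C >= 4")
    i = np.arange(C)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    # cos(theta) in (0, 1): frontal hemisphere only, poles excluded
    cos_t = (i + 0.5) / C
    theta = np.arccos(cos_t)
    phi = 2.0 * np.pi * i / golden
    dirs = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    return dirs


def expressive_indices(C: int, n_expr: int = 8) -> np.ndarray:
    """Evenly spread subset of landmark indices carrying expression signal."""
    n_expr = min(n_expr, C)
    return np.unique(np.linspace(0, C - 1, n_expr).round().astype(int))


def expression_patterns(n_classes: int, n_expr: int = 8, amplitude: float = 10.0) -> np.ndarray:
    """(n_classes, n_expr) signed radial amplitudes, pairwise distinct.

    Class patterns are fixed sign/zero codes scaled by ``amplitude`` (mm);
    the last class of a 7-class vocabulary is the all-zero "neutral".
    """
    codes = np.array(
        [
            [+1, -1, +1, -1, +1, -1, +1, -1],
            [-1, +1, +1, -1, -1, +1, -1, +1],
            [+1, +1, -1, -1, +1, +1, -1, -1],
            [-1, -1, -1, +1, +1, +1, +1, -1],
            [+1, -1, -1, +1, -1, +1, +1, +1],
            [-1, +1, -1, +1, +1, -1, -1, +1],
            [0, 0, 0, 0, 0, 0, 0, 0],
        ],
        dtype=float,
    )
    if n_classes > len(codes):
        raise ValueError(f"at most {len(codes)} classes supported")
    return amplitude * codes[:n_classes, :n_expr]


@dataclass
class FaceSpec:
    """Everything needed to deterministically synthesize one face sample."""

    subject_seed: int
    sample_seed: int
    class_id: int
    n_classes: int = 7
    n_points: int = 8000
    C: int = 22
    base_axes: tuple[float, float, float] = (75.0, 90.0, 80.0)  # mm
    axis_jitter: float = 0.08  # per-subject relative sd of semi-axes
    n_subject_bumps: int = 8
    bump_amplitude: float = 2.5  # mm, sd of signed bump heights
    bump_width: float = 0.5  # rad, angular width of subject bumps
    expression_amplitude: float = 10.0  # mm, typical prototypical-expression displacement
    expression_width: float = 0.18  # rad, local: comparable to the KNN patch
    noise_sd: float = 0.5  # mm isotropic point jitter
    sampling_bias: float = 1.0  # frontal oversampling exponent
    rotation_max_deg: float = 10.0
    translation_max: float = 20.0  # mm

    def __post_init__(self) -> None:
        if min(self.base_axes) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")
        if not 0 <= self.class_id < self.n_classes:
            raise ValueError("class_id out of range")


@dataclass
class DatasetSpec:
    """Deterministic expansion into a list of FaceSpec."""

    n_subjects: int = 14
    n_classes: int = 7
    samples_per_subject_class: int = 1
    C: int = 22
    seed: int = 0
    face_kwargs: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("need at least 10 subjects for split feasibility")
        if not 2 <= self.n_classes <= 7:
            raise ValueError("n_classes must be in [2, 7]")

    @property
    def class_names(self) -> tuple[str, ...]:
        return (CLASS_NAMES_7 if self.n_classes == 7 else CLASS_NAMES_6)[: self.n_classes]

    def face_specs(self) -> list[tuple[FaceSpec, str, str]]:
        """[(spec, subject_id, class_label), ...] in manifest order."""
        out = []
        for s in range(self.n_subjects):
            subj_seed = int(
                np.random.SeedSequence([self.seed, s]).generate_state(1)[0] % (2**31)
            )
            for c in range(self.n_classes):
                for r in range(self.samples_per_subject_class):
                    samp_seed = int(
                        np.random.SeedSequence([self.seed, s, c, r]).generate_state(1)[0]
                        % (2**31)
                    )
                    spec = FaceSpec(
                        subject_seed=subj_seed,
                        sample_seed=samp_seed,
                        class_id=c,
                        n_classes=self.n_classes,
                        C=self.C,
                        **self.face_kwargs,
                    )
                    out.append((spec, f"subj{s:03d}", self.class_names[c]))
        return out


def _sphere_directions(rng: np.random.Generator, n: int, bias: float) -> np.ndarray:
    """Unit directions, oversampling the frontal (z > 0) side for bias > 0.

    Rejection sampling with weight ((1 + z) / 2)^bias emulates a frontal
    scanner seeing the far side of the head only obliquely.
    """
    dirs = np.empty((0, 3))
    while len(dirs) < n:
        m = max(2 * (n - len(dirs)), 64)
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        if bias > 0:
            keep = rng.random(m) < ((1.0 + v[:, 2]) / 2.0) ** bias
            v = v[keep]
        dirs = np.vstack([dirs, v])
    return dirs[:n]


def _radial_field(
    dirs: np.ndarray,
    axes: np.ndarray,
    bump_dirs: np.ndarray,
    bump_amps: np.ndarray,
    bump_width: float,
    expr_dirs: np.ndarray,
    expr_amps: np.ndarray,
    expr_width: float,
) -> np.ndarray:
    """Radius along each unit direction: ellipsoid + subject bumps + expression."""
    inv = np.sqrt((dirs**2 / axes**2).sum(axis=1))
    r = 1.0 / inv  # exact ellipsoid radius along each direction
    for bd, ba, bw in [(bump_dirs, bump_amps, bump_width), (expr_dirs, expr_amps, expr_width)]:
        if len(bd) == 0:
            continue
        cosang = np.clip(dirs @ bd.T, -1.0, 1.0)
        ang = np.arccos(cosang)  # (n, n_centers)
        r = r + (np.exp(-(ang**2) / (2.0 * bw**2)) @ ba)
    return r


def random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    """Uniform random axis, angle uniform in [0, max_deg]; Rodrigues form."""
    if max_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(0.0, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def generate_face(spec: FaceSpec) -> tuple[PointCloud, LandmarkSet, str]:
    """Synthesize one sample: (cloud, landmarks, class label).

    Landmarks are the template directions pushed through the same radial
    deformation and rigid motion as the surface points (they ride the
    surface), so expression signal reaches both the descriptor and the
    landmark-graph stages.
    """
    subj_rng = np.random.default_rng(spec.subject_seed)
    samp_rng = np.random.default_rng(spec.sample_seed)

    axes = np.asarray(spec.base_axes) * (
        1.0 + spec.axis_jitter * subj_rng.standard_normal(3)
    )
    if min(axes) <= 0:
        raise ValueError("degenerate ellipsoid semi-axes after jitter")
    bump_dirs = _sphere_directions(subj_rng, spec.n_subject_bumps, bias=0.0)
    bump_amps = spec.bump_amplitude * subj_rng.standard_normal(spec.n_subject_bumps)

    template = landmark_template(spec.C)
    expr_idx = expressive_indices(spec.C)
    patterns = expression_patterns(
        spec.n_classes, n_expr=len(expr_idx), amplitude=spec.expression_amplitude
    )
    expr_dirs = template[expr_idx]
    expr_amps = patterns[spec.class_id]

    dirs = _sphere_directions(samp_rng, spec.n_points, spec.sampling_bias)
    r = _radial_field(
        dirs, axes, bump_dirs, bump_amps, spec.bump_width, expr_dirs, expr_amps,
        spec.expression_width,
    )
    pts = dirs * r[:, None]
    if spec.noise_sd > 0:
        pts = pts + spec.noise_sd * samp_rng.standard_normal(pts.shape)

    lr = _radial_field(
        template, axes, bump_dirs, bump_amps, spec.bump_width, expr_dirs, expr_amps,
        spec.expression_width,
    )
    lmk = template * lr[:, None]

    R = random_rotation(samp_rng, spec.rotation_max_deg)
    tvec = samp_rng.uniform(-spec.translation_max, spec.translation_max, size=3)
    pts = pts @ R.T + tvec
    lmk = lmk @ R.T + tvec

    label = (CLASS_NAMES_7 if spec.n_classes == 7 else CLASS_NAMES_6)[spec.class_id]
    return (
        PointCloud(pts, sample_id=f"s{spec.sample_seed}", label=label),
        LandmarkSet(lmk),
        label,
    )


def generate_dataset(dspec: DatasetSpec, out_dir: str | Path, force: bool = False) -> Path:
    """Write all samples (XYZ clouds + landmark files) and a CSV manifest.

    Returns the manifest path. Refuses a non-empty directory unless
    ``force``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (pass force=True to overwrite)")
    records = []
    for i, (spec, subject, label) in enumerate(dspec.face_specs()):
        cloud, lmk, _ = generate_face(spec)
        cloud_path = out_dir / f"sample{i:04d}_{subject}_{label}.xyz"
        lmk_path = out_dir / f"sample{i:04d}_{subject}_{label}.lmk"
        write_pointcloud(cloud, cloud_path)
        write_landmarks(lmk, lmk_path)
        records.append(
            ManifestRecord(
                cloud_path=str(cloud_path),
                landmark_path=str(lmk_path),
                subject_id=subject,
                class_label=label,
            )
        )
    manifest = DatasetManifest(records, class_names=list(dspec.class_names))
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    return manifest_path


def perturb_landmarks(
    landmarks: LandmarkSet,
    fraction: float = 0.10,
    seed: int | np.random.Generator = 0,
    as_std: bool = False,
) -> LandmarkSet:
    """Add white Gaussian noise to every landmark coordinate.

    The noise variance is ``fraction`` times the mean pairwise Euclidean
    distance of the landmark set (taken literally as a variance; pass
    ``as_std=True`` to read the target as a standard deviation instead).
    ``fraction=0`` returns the landmarks unchanged.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    if fraction == 0:
        return LandmarkSet(landmarks.coords.copy(), names=landmarks.names)
    coords = landmarks.coords
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    iu = np.triu_indices(len(coords), k=1)
    mean_pair = dist[iu].mean()
    target = fraction * mean_pair
    sd = target if as_std else np.sqrt(target)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = coords + sd * rng.standard_normal(coords.shape)
    return LandmarkSet(noisy, names=landmarks.names)


def perturb_cloud(
    cloud: PointCloud,
    landmarks: LandmarkSet,
    rotation_deg: float = 0.0,
    translation: float = 0.0,
    point_noise_sd: float = 0.0,
    resample_fraction: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[PointCloud, LandmarkSet]:
    """Nuisance perturbations applied in order: random rotation (axis-angle,
    up to rotation_deg), random translation (uniform in a cube of side
    2*translation), per-point Gaussian jitter, random subsampling to
    ``resample_fraction``. The rigid part also moves the landmarks."""
    if not 0 < resample_fraction <= 1:
        raise ValueError("resample_fraction must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = random_rotation(rng, rotation_deg)
    tvec = rng.uniform(-translation, translation, size=3) if translation > 0 else np.zeros(3)
    pts = cloud.points @ R.T + tvec
    lmk = landmarks.coords @ R.T + tvec
    if point_noise_sd > 0:
        pts = pts + point_noise_sd * rng.standard_normal(pts.shape)
    if resample_fraction < 1:
        n_keep = max(1, int(round(resample_fraction * len(pts))))
        keep = np.sort(rng.choice(len(pts), size=n_keep, replace=False))
        pts = pts[keep]
    return (
        PointCloud(pts, sample_id=cloud.sample_id, label=cloud.label),
        LandmarkSet(lmk, names=landmarks.names),
    )
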