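import hashlib

import numpy as np
import pytest

from facescatter import (
    DatasetSpec,
    FaceSpec,
    LandmarkSet,
    generate_dataset,
    generate_face,
    perturb_cloud,
    perturb_landmarks,
    read_manifest,
)
from facescatter.spectral import affinity_matrix, eigendecompose, laplacian
from facescatter.synth import expression_patterns, landmark_template


def clean_spec(class_id=0, **kw):
    defaults = dict(
        subject_seed=1, sample_seed=2, class_id=class_id, n_points=2000,
        axis_jitter=0.0, bump_amplitude=0.0, expression_amplitude=0.0,
        noise_sd=0.0, rotation_max_deg=0.0, translation_max=0.0, sampling_bias=0.0,
    )
    defaults.update(kw)
    return FaceSpec(**defaults)


class TestGenerateFace:
    def test_deterministic(self):
        spec = FaceSpec(subject_seed=3, sample_seed=9, class_id=2, n_points=500)
        c1, l1, lab1 = generate_face(spec)
        c2, l2, lab2 = generate_face(spec)
        np.testing.assert_array_equal(c1.points, c2.points)
        np.testing.assert_array_equal(l1.coords, l2.coords)
        assert lab1 == lab2

    def test_undeformed_points_on_ellipsoid(self):
        spec = clean_spec()
        cloud, lmk, _ = generate_face(spec)
        a, b, c = spec.base_axes
        q = (cloud.points[:, 0] / a) ** 2 + (cloud.points[:, 1] / b) ** 2 + (
            cloud.points[:, 2] / c
        ) ** 2
        assert np.abs(q - 1).max() < 1e-9
        ql = (lmk.coords[:, 0] / a) ** 2 + (lmk.coords[:, 1] / b) ** 2 + (
            lmk.coords[:, 2] / c
        ) ** 2
        assert np.abs(ql - 1).max() < 1e-9

    def test_opposite_expression_signs_shift_local_radius(self):
        # two classes whose amplitude patterns differ in sign at an
        # expressive landmark: mean radial coordinate near that landmark
        # moves with the pattern sign
        patterns = expression_patterns(2)
        j = int(np.flatnonzero(np.sign(patterns[0]) != np.sign(patterns[1]))[0])
        template = landmark_template(22)
        from facescatter.synth import expressive_indices

        direction = template[expressive_indices(22)[j]]
        means = {}
        for cid in (0, 1):
            spec = clean_spec(class_id=cid, expression_amplitude=10.0, n_points=4000)
            cloud, _, _ = generate_face(spec)
            u = cloud.points / np.linalg.norm(cloud.points, axis=1, keepdims=True)
            near = np.arccos(np.clip(u @ direction, -1, 1)) < spec.expression_width
            assert near.sum() > 20
            means[cid] = np.linalg.norm(cloud.points[near], axis=1).mean()
        diff = means[0] - means[1]
        assert np.sign(diff) == np.sign(patterns[0][j] - patterns[1][j])
        assert abs(diff) > 1.0  # mm

    def test_landmarks_ride_expression(self):
        base = clean_spec(class_id=0)
        expr = clean_spec(class_id=0, expression_amplitude=10.0)
        _, l0, _ = generate_face(base)
        _, l1, _ = generate_face(expr)
        assert np.abs(l1.coords - l0.coords).max() > 1.0

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError):
            FaceSpec(subject_seed=1, sample_seed=1, class_id=0, base_axes=(0.0, 1.0, 1.0))


class TestGenerateDataset:
    def test_counts_and_balance(self, tmp_path):
        dspec = DatasetSpec(n_subjects=10, n_classes=7, seed=5,
                            face_kwargs={"n_points": 200})
        manifest_path = generate_dataset(dspec, tmp_path / "d")
        man = read_manifest(manifest_path)
        assert len(man) == 70
        labels = man.labels()
        assert all(labels.count(n) == 10 for n in man.class_names)
        assert len(man.class_names) == 7

    def test_same_seed_identical_files(self, tmp_path):
        dspec = DatasetSpec(n_subjects=10, n_classes=2, seed=9,
                            face_kwargs={"n_points": 100})
        p1 = generate_dataset(dspec, tmp_path / "a")
        p2 = generate_dataset(dspec, tmp_path / "b")

        def digest(root):
            h = hashlib.sha1()
            for f in sorted(root.parent.iterdir()):
                h.update(f.name.encode())
                h.update(f.read_bytes())
            return h.hexdigest()

        assert digest(p1) == digest(p2)

    def test_refuses_nonempty_dir(self, tmp_path):
        d = tmp_path / "d"
        d.mkdir()
        (d / "junk.txt").write_text("x")
        dspec = DatasetSpec(n_subjects=10, n_classes=2, face_kwargs={"n_points": 50})
        with pytest.raises(FileExistsError):
            generate_dataset(dspec, d)
        generate_dataset(dspec, d, force=True)  # force overrides


class TestPerturbLandmarks:
    def test_fraction_zero_identity(self, rng):
        lm = LandmarkSet(rng.normal(size=(22, 3)))
        out = perturb_landmarks(lm, fraction=0.0, seed=3)
        np.testing.assert_array_equal(out.coords, lm.coords)

    def test_unit_square_closed_form(self):
        corners = LandmarkSet(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        )
        coords = corners.coords
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        iu = np.triu_indices(4, 1)
        mean_pair = d[iu].mean()
        assert mean_pair == pytest.approx((4 + 2 * np.sqrt(2)) / 6, abs=1e-12)

    def test_empirical_variance_matches_rule(self, rng):
        corners = LandmarkSet([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        target_var = 0.10 * (4 + 2 * np.sqrt(2)) / 6
        draws = np.stack(
            [perturb_landmarks(corners, 0.10, seed=s).coords - corners.coords
             for s in range(3000)]
        )
        emp = draws.var()
        assert emp == pytest.approx(target_var, rel=0.03)

    def test_as_std_interpretation(self, rng):
        lm = LandmarkSet(rng.normal(scale=5, size=(10, 3)))
        rng2 = np.random.default_rng(0)
        a = perturb_landmarks(lm, 0.1, seed=1, as_std=False)
        b = perturb_landmarks(lm, 0.1, seed=1, as_std=True)
        # same underlying draws, different scale
        ra = a.coords - lm.coords
        rb = b.coords - lm.coords
        ratio = rb / ra
        assert np.allclose(ratio, ratio.flat[0])

    def test_deterministic_under_seed(self, rng):
        lm = LandmarkSet(rng.normal(size=(5, 3)))
        a = perturb_landmarks(lm, 0.2, seed=7)
        b = perturb_landmarks(lm, 0.2, seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestPerturbCloud:
    def test_identity_at_zero_magnitudes(self, rng):
        from facescatter import PointCloud

        cloud = PointCloud(rng.normal(size=(50, 3)))
        lm = LandmarkSet(rng.normal(size=(5, 3)))
        c2, l2 = perturb_cloud(cloud, lm, seed=1)
        np.testing.assert_allclose(c2.points, cloud.points, atol=1e-12)
        np.testing.assert_allclose(l2.coords, lm.coords, atol=1e-12)

    def test_rotation_preserves_pairwise_distances_and_spectrum(self, rng):
        from facescatter import PointCloud

        cloud = PointCloud(rng.normal(size=(50, 3)))
        lm = LandmarkSet(rng.normal(scale=10, size=(8, 3)))
        _, l2 = perturb_cloud(cloud, lm, rotation_deg=45.0, seed=2)

        def pdist(c):
            return np.linalg.norm(c[:, None] - c[None, :], axis=-1)

        np.testing.assert_allclose(pdist(l2.coords), pdist(lm.coords), atol=1e-9)
        e1 = eigendecompose(laplacian(affinity_matrix(lm)), k=8).eigenvalues
        e2 = eigendecompose(laplacian(affinity_matrix(l2)), k=8).eigenvalues
        np.testing.assert_allclose(e1, e2, atol=1e-9)

    def test_resampling_bounds(self, rng):
        from facescatter import PointCloud

        cloud = PointCloud(rng.normal(size=(100, 3)))
        lm = LandmarkSet(rng.normal(size=(4, 3)))
        c2, _ = perturb_cloud(cloud, lm, resample_fraction=0.5, seed=3)
        assert len(c2) == 50
        with pytest.raises(ValueError):
            perturb_cloud(cloud, lm, resample_fraction=0.0)
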