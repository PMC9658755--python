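"""Generate synthetic expressive-face point clouds and inspect their geometry.

Each sample is an ellipsoidal "head" with subject-specific bumps, a
class-specific local deformation near designated expressive landmarks, point
jitter and a random head pose; landmarks ride the deformed surface.
"""

import numpy as np

from facescatter import FaceSpec, generate_face

for class_id, name in [(0, "AN"), (3, "HA"), (6, "NE")]:
    spec = FaceSpec(subject_seed=7, sample_seed=100 + class_id, class_id=class_id)
    cloud, landmarks, label = generate_face(spec)
    radii = np.linalg.norm(cloud.points - cloud.points.mean(axis=0), axis=1)
    print(
        f"class {label}: {len(cloud)} points, C={landmarks.C} landmarks, "
        f"radius {radii.mean():.1f} +- {radii.std():.1f} mm"
    )

# same spec -> bit-identical sample (the generator is a pure function of its seeds)
a, _, _ = generate_face(FaceSpec(subject_seed=7, sample_seed=1, class_id=0))
b, _, _ = generate_face(FaceSpec(subject_seed=7, sample_seed=1, class_id=0))
print("deterministic:", np.array_equal(a.points, b.points))
# The radii differ slightly between classes because each expression deforms
# the surface near its expressive landmarks; determinism is what makes the
# study protocols reproducible.
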