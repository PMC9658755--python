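"""Readers and writers for point clouds, landmark sets, manifests and features.

All formats are plain ASCII text: XYZ (whitespace-separated coordinates, one
point per line), PLY 1.0 (vertex elements only, faces ignored), OBJ (``v``
lines only) for clouds; three small landmark dialects; a CSV manifest tying
samples to landmark files and class labels; HDF5 or CSV feature containers.

Coordinates are kept in the input length units (typically mm); no rescaling
happens at the I/O layer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "PointCloud",
    "LandmarkSet",
    "DatasetManifest",
    "ManifestRecord",
    "read_pointcloud",
    "write_pointcloud",
    "read_landmarks",
    "write_landmarks",
    "read_manifest",
    "write_manifest",
    "save_features",
    "load_features",
    "FingerprintMismatchError",
]


@dataclass
class PointCloud:
    """An unordered 3D scan stored in file order.

    points : (N, 3) float array, N >= 1, all finite.
    """

    points: np.ndarray
    sample_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(self.points) < 1:
            raise ValueError("a point cloud needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class LandmarkSet:
    """Ordered anatomical anchor points (22 or 83 in the common protocols)."""

    coords: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be a (C, 3) array")
        if len(self.coords) < 3:
            raise ValueError("at least 3 landmarks required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")
        if self.names is not None and len(self.names) != len(self.coords):
            raise ValueError("names length must match landmark count")

    @property
    def C(self) -> int:
        return len(self.coords)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class ManifestRecord:
    cloud_path: str
    landmark_path: str
    subject_id: str
    class_label: str


@dataclass
class DatasetManifest:
    """Sample table: cloud file, landmark file, subject id, class label."""

    records: list[ManifestRecord]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            self.class_names = sorted({r.class_label for r in self.records})
        missing = {r.class_label for r in self.records} - set(self.class_names)
        if missing:
            raise ValueError(f"labels outside vocabulary: {sorted(missing)}")
        if any(not r.subject_id for r in self.records):
            raise ValueError("every record needs a non-empty subject_id")

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id)
        return list(seen)

    def labels(self) -> list[str]:
        return [r.class_label for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# point clouds


def _parse_coord_line(line: str, lineno: int, path: str, n_fields: int = 3) -> list[float]:
    parts = line.split()
    if len(parts) < n_fields:
        raise ValueError(f"{path}:{lineno}: expected {n_fields} fields, got {len(parts)}")
    try:
        return [float(x) for x in parts[:n_fields]]
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-numeric coordinate: {exc}") from None


def _read_xyz(path: Path) -> np.ndarray:
    pts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            pts.append(_parse_coord_line(line, lineno, str(path)))
    return np.asarray(pts, dtype=float)


def _read_ply(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header != b"ply":
            raise ValueError(f"{path}: not a PLY file (missing 'ply' magic)")
        n_vertex = None
        lineno = 1
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise ValueError(f"{path}: PLY header never ends")
            line = raw.decode("ascii", errors="replace").strip()
            if line.startswith("format"):
                if "ascii" not in line:
                    raise ValueError(f"{path}: binary PLY not supported, ASCII only")
            elif line.startswith("element vertex"):
                n_vertex = int(line.split()[2])
            elif line == "end_header":
                break
        if n_vertex is None:
            raise ValueError(f"{path}: PLY header lacks 'element vertex'")
        pts = []
        for i in range(n_vertex):
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise ValueError(f"{path}: expected {n_vertex} vertices, file ended at {i}")
            pts.append(_parse_coord_line(raw.decode("ascii"), lineno, str(path)))
    return np.asarray(pts, dtype=float)


def _read_obj(path: Path) -> np.ndarray:
    pts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line.startswith("v "):
                continue
            pts.append(_parse_coord_line(line[2:], lineno, str(path)))
    return np.asarray(pts, dtype=float)


_CLOUD_READERS = {"xyz": _read_xyz, "ply": _read_ply, "obj": _read_obj}


def read_pointcloud(path: str | Path, format: str = "auto") -> PointCloud:
    """Read an ASCII point cloud; PLY faces / OBJ faces are ignored.

    ``format`` is one of ``ply``, ``obj``, ``xyz`` or ``auto`` (by extension,
    unknown extensions fall back to xyz).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = path.suffix.lstrip(".").lower()
        if format not in _CLOUD_READERS:
            format = "xyz"
    if format not in _CLOUD_READERS:
        raise ValueError(f"unknown point cloud format {format!r}")
    pts = _CLOUD_READERS[format](path)
    if len(pts) == 0:
        raise ValueError(f"{path}: no points found")
    return PointCloud(pts, sample_id=path.stem)


def write_pointcloud(cloud: PointCloud, path: str | Path, format: str = "xyz") -> None:
    """Write an ASCII cloud with full float precision (%.10g)."""
    path = Path(path)
    if format == "xyz":
        with open(path, "w") as fh:
            for p in cloud.points:
                fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
    elif format == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(cloud)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write("end_header\n")
            for p in cloud.points:
                fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
    else:
        raise ValueError(f"unsupported output format {format!r}")


# ---------------------------------------------------------------------------
# landmarks


def read_landmarks(path: str | Path, dialect: str = "bare_xyz") -> LandmarkSet:
    """Read a landmark file. ``#`` lines are comments.

    Dialects: ``bare_xyz`` (``x y z``), ``name_xyz`` (``label x y z``),
    ``index_xyz`` (``i x y z``, BU-3DFE .bnd style; the index is discarded).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("bare_xyz", "name_xyz", "index_xyz"):
        raise ValueError(f"unknown landmark dialect {dialect!r}")
    coords: list[list[float]] = []
    names: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if dialect == "bare_xyz":
                coords.append(_parse_coord_line(line, lineno, str(path)))
            else:
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
                try:
                    coords.append([float(x) for x in parts[1:4]])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric coordinate: {exc}") from None
                names.append(parts[0])
    if len(coords) < 3:
        raise ValueError(f"{path}: at least 3 landmarks required, got {len(coords)}")
    return LandmarkSet(np.asarray(coords), names=names if dialect == "name_xyz" else None)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in landmarks.coords:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")


# ---------------------------------------------------------------------------
# manifests

_MANIFEST_COLUMNS = ("cloud", "landmarks", "subject", "label")


def read_manifest(path: str | Path, check_paths: bool = True) -> DatasetManifest:
    """Read a CSV manifest with columns cloud,landmarks,subject,label.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _MANIFEST_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: manifest missing columns {missing}")
        records = []
        for row in reader:
            records.append(
                ManifestRecord(
                    cloud_path=str((path.parent / row["cloud"]).resolve()),
                    landmark_path=str((path.parent / row["landmarks"]).resolve()),
                    subject_id=row["subject"],
                    class_label=row["label"],
                )
            )
    if check_paths:
        dangling = [
            p
            for r in records
            for p in (r.cloud_path, r.landmark_path)
            if not Path(p).exists()
        ]
        if dangling:
            raise FileNotFoundError(f"{path}: missing referenced files: {dangling}")
    return DatasetManifest(records)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for r in manifest.records:
            cloud = Path(r.cloud_path)
            lmk = Path(r.landmark_path)
            try:
                cloud = cloud.relative_to(path.parent.resolve())
                lmk = lmk.relative_to(path.parent.resolve())
            except ValueError:
                pass
            writer.writerow([str(cloud), str(lmk), r.subject_id, r.class_label])


# ---------------------------------------------------------------------------
# feature containers


class FingerprintMismatchError(RuntimeError):
    """Raised when a feature container was produced under a different config."""


def save_features(
    features: np.ndarray,
    path: str | Path,
    *,
    fingerprint: str = "",
    sample_ids: Sequence[str] | None = None,
    labels: Sequence[str] | None = None,
    subjects: Sequence[str] | None = None,
    format: str = "hdf5",
) -> None:
    """Persist a (samples x dims) feature matrix plus manifest metadata.

    The config fingerprint travels with the container so that features from
    mismatched pipeline settings cannot be silently mixed.
    """
    features = np.asarray(features, dtype=float)
    path = Path(path)
    n = len(features)
    sample_ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    labels = list(labels) if labels is not None else [""] * n
    subjects = list(subjects) if subjects is not None else [""] * n
    if not (len(sample_ids) == len(labels) == len(subjects) == n):
        raise ValueError("metadata length must match feature row count")
    if format == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("features", data=features)
            fh.create_dataset("sample_ids", data=np.array(sample_ids, dtype="S"))
            fh.create_dataset("labels", data=np.array(labels, dtype="S"))
            fh.create_dataset("subjects", data=np.array(subjects, dtype="S"))
            fh.attrs["fingerprint"] = fingerprint
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(f"# fingerprint={fingerprint}\n")
            writer = csv.writer(fh)
            writer.writerow(
                ["sample_id", "subject", "label"] + [f"f{i}" for i in range(features.shape[1])]
            )
            for sid, sub, lab, row in zip(sample_ids, subjects, labels, features):
                writer.writerow([sid, sub, lab] + [f"{v:.17g}" for v in row])
    else:
        raise ValueError(f"unsupported feature format {format!r}")


def load_features(
    path: str | Path,
    *,
    expect_fingerprint: str | None = None,
    strict: bool = True,
    format: str = "auto",
) -> tuple[np.ndarray, dict]:
    """Load a feature container; returns (matrix, metadata dict)."""
    path = Path(path)
    if format == "auto":
        format = "csv" if path.suffix.lower() == ".csv" else "hdf5"
    if format == "hdf5":
        with h5py.File(path, "r") as fh:
            features = fh["features"][()]
            meta = {
                "fingerprint": fh.attrs.get("fingerprint", ""),
                "sample_ids": [s.decode() for s in fh["sample_ids"][()]],
                "labels": [s.decode() for s in fh["labels"][()]],
                "subjects": [s.decode() for s in fh["subjects"][()]],
            }
    else:
        with open(path, newline="") as fh:
            first = fh.readline().strip()
            fingerprint = first.split("=", 1)[1] if first.startswith("# fingerprint=") else ""
            reader = csv.reader(fh)
            header = next(reader)
            n_meta = 3
            rows, sids, subs, labs = [], [], [], []
            for row in reader:
                sids.append(row[0])
                subs.append(row[1])
                labs.append(row[2])
                rows.append([float(v) for v in row[n_meta:]])
            features = np.asarray(rows, dtype=float)
            meta = {
                "fingerprint": fingerprint,
                "sample_ids": sids,
                "labels": labs,
                "subjects": subs,
            }
            del header
    if (
        strict
        and expect_fingerprint is not None
        and meta["fingerprint"] != expect_fingerprint
    ):
        raise FingerprintMismatchError(
            f"feature container fingerprint {meta['fingerprint']!r} does not match "
            f"expected {expect_fingerprint!r}"
        )
    return features, meta
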