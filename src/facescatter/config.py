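"""YAML run configuration: one nested mapping covering every stage.

Unknown keys are rejected (typos in experiment configs must fail loudly,
not silently fall back to defaults). The canonical JSON serialization of
the merged config is hashed into the fingerprint that every on-disk
artifact carries.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .classify import SplitPlan
from .density import DensityParams
from .pipeline import PipelineConfig
from .scattering import MomentConfig
from .sparsenet import SparseLayerConfig, TrainConfig

__all__ = ["RunConfig", "load_config"]

_SCHEMA = {
    "seed": int,
    "density": {"K": int, "M": int, "sigma": (float, type(None)), "alpha": float,
                "half_width": (float, type(None)), "normalize": bool},
    "spectral": {"epsilon": (float, type(None)), "k": int, "which": str},
    "scattering": {"J": int, "Q": list, "second_order": bool, "lowpass_moments": bool},
    "train": {"optimizer": str, "learning_rate": float, "batch_size": int,
              "weight_decay": float, "epochs": int, "momentum": float, "seed": int},
    "sparse": {"dictionary_size": int, "iterations": int, "threshold": float},
    "splits": {"repeats": int, "fractions": list, "seed": int},
    "synth": {"n_subjects": int, "n_classes": int, "samples_per_subject_class": int,
              "C": int, "n_points": int, "seed": int},
}


def _check_keys(data: dict, schema: dict, path: str = "") -> None:
    for key, val in data.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(schema[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {where} must be a mapping")
            _check_keys(val, schema[key], where)


class RunConfig:
    """Merged configuration with typed accessors for each stage."""

    def __init__(self, data: dict | None = None):
        data = data or {}
        _check_keys(data, _SCHEMA)
        self.data = data

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def _sect(self, name: str) -> dict:
        return dict(self.data.get(name, {}))

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    def density_params(self) -> DensityParams:
        d = self._sect("density")
        return DensityParams(
            K=d.get("K", 64), M=d.get("M", 10), sigma=d.get("sigma"),
            alpha=d.get("alpha", 1.0), half_width=d.get("half_width"),
            normalize=d.get("normalize", True),
        )

    def pipeline_config(self) -> PipelineConfig:
        s = self._sect("spectral")
        sc = self._sect("scattering")
        return PipelineConfig(
            density=self.density_params(),
            epsilon=s.get("epsilon"),
            k=s.get("k", 6),
            which=s.get("which", "smallest_magnitude"),
            J=sc.get("J", 0),
            moments=MomentConfig(
                Q=tuple(sc.get("Q", (0.5, 1.0, 2.0))),
                include_second_order=sc.get("second_order", True),
                include_lowpass_moments=sc.get("lowpass_moments", True),
            ),
        )

    def train_config(self) -> TrainConfig:
        t = self._sect("train")
        t.setdefault("seed", self.seed)
        return TrainConfig(**t)

    def sparse_config(self) -> SparseLayerConfig:
        return SparseLayerConfig(**self._sect("sparse"))

    def split_plan(self) -> SplitPlan:
        s = self._sect("splits")
        return SplitPlan(
            repeats=s.get("repeats", 10),
            fractions=tuple(s.get("fractions", (0.70, 0.20, 0.10))),
            seed=s.get("seed", self.seed),
        )

    def fingerprint(self) -> str:
        merged = {"pipeline": self.pipeline_config().fingerprint(), "data": self.data}
        return hashlib.sha1(json.dumps(merged, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    return RunConfig.from_yaml(path) if path else RunConfig()
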