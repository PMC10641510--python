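"""Pipeline configuration: one declarative object, YAML round-trip, seeds.

Every stochastic stage derives its own seed deterministically from the
master seed and the stage name, so a full run is reproducible from the
config alone and stages can be re-run in isolation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .netmetrics import ThresholdGrid
from .preprocess import PreprocessConfig
from .simcohort import CohortEffects, LatentStructure, SimConfig

__all__ = ["PipelineConfig", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """All knobs for simulate -> preprocess -> connect -> graph -> stats."""

    seed: int = 0
    n_patients: int = 13
    n_controls: int = 26
    sim: SimConfig = field(default_factory=SimConfig)
    effects: CohortEffects = field(default_factory=CohortEffects)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_bootstrap_windows: int = 200
    window_s: float = 60.0
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    n_random_graphs: int = 100
    n_permutations: int = 2000
    out_dir: str = "nirsnet_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if isinstance(sim.get("latent_structure"), dict):
                ls = dict(sim["latent_structure"])
                if "planted_edges" in ls:
                    ls["planted_edges"] = tuple(tuple(e) for e in ls["planted_edges"])
                sim["latent_structure"] = LatentStructure(**ls)
            for key in ("wavelengths", "isi_range_s"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "artifact_spec" in sim:
                sim["artifact_spec"] = tuple(tuple(a) for a in sim["artifact_spec"])
            d["sim"] = SimConfig(**sim)
        if "effects" in d and isinstance(d["effects"], dict):
            d["effects"] = CohortEffects(**d["effects"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            pp = dict(d["preprocess"])
            for key in ("cardiac_band", "filter_band", "dpf_override"):
                if pp.get(key) is not None:
                    pp[key] = tuple(pp[key])
            if pp.get("extinction_override") is not None:
                pp["extinction_override"] = tuple(tuple(r) for r in pp["extinction_override"])
            d["preprocess"] = PreprocessConfig(**pp)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = ThresholdGrid(**d["grid"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
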