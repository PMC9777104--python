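"""Run configuration: one declarative YAML file covering every stage.

Sections mirror the per-module config dataclasses (augment, patches,
encoder, contrastive, segmentation) plus a global seed and output
directory.  Unknown sections or keys are rejected rather than ignored, and
the fully resolved configuration is written next to every run's outputs so
the two-stage training is reproducible from the snapshot alone.

The defaults are the reference training protocol: contrastive stage with
SGD (lr 0.001, 50 epochs, batch 2, temperature 0.07) on 224x224 views;
segmentation stage with Adam (lr 0.0002, betas (0.5, 0.999), 100 epochs,
batch 4, loss weight gamma 0.4, threshold 0.5); patch extraction
1024 -> 4 x 512 tiles -> 200 random 256 crops per tile.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .contrastive import ContrastiveConfig
from .data_pipeline import AugmentConfig, PatchExtractionConfig
from .segnet import SegConfig
from .sie_encoder import EncoderConfig

__all__ = ["RunConfig", "rng_stream"]

_SUB_STREAMS = {"data": 0, "patches": 1, "pretrain": 2, "train": 3, "predict": 4}


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """A named child stream of the global seed, so stochastic stages are
    isolated from each other."""
    if name not in _SUB_STREAMS:
        raise ValueError(f"unknown rng stream {name!r}; known: {sorted(_SUB_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SUB_STREAMS[name],)))


def _build(cls, section: str, data: dict):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - field_names)
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {unknown}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**coerced)


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    patches: PatchExtractionConfig = dataclasses.field(default_factory=PatchExtractionConfig)
    encoder: EncoderConfig = dataclasses.field(default_factory=lambda: EncoderConfig.from_preset("full"))
    contrastive: ContrastiveConfig = dataclasses.field(default_factory=ContrastiveConfig)
    segmentation: SegConfig = dataclasses.field(default_factory=SegConfig)

    _SECTIONS = {
        "augment": AugmentConfig,
        "patches": PatchExtractionConfig,
        "encoder": EncoderConfig,
        "contrastive": ContrastiveConfig,
        "segmentation": SegConfig,
    }

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: dict, **overrides) -> "RunConfig":
        unknown = sorted(set(raw) - set(cls._SECTIONS) - {"seed", "out_dir"})
        if unknown:
            raise ValueError(f"unknown config sections: {unknown}")
        kw = {}
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        if "out_dir" in raw:
            kw["out_dir"] = str(raw["out_dir"])
        for name, section_cls in cls._SECTIONS.items():
            if name in raw:
                if name == "encoder" and "preset" in raw[name]:
                    data = dict(raw[name])
                    preset = data.pop("preset")
                    extra = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
                    known = {f.name for f in dataclasses.fields(EncoderConfig)}
                    bad = sorted(set(extra) - known)
                    if bad:
                        raise ValueError(f"unknown keys in config section 'encoder': {bad}")
                    kw[name] = EncoderConfig.from_preset(preset, **extra)
                else:
                    kw[name] = _build(section_cls, name, raw[name])
        cfg = cls(**kw)
        for dotted, value in overrides.items():
            cfg = cfg._override(dotted, value)
        return cfg

    def _override(self, dotted: str, value) -> "RunConfig":
        if "." in dotted:
            section, key = dotted.split(".", 1)
            if section not in self._SECTIONS:
                raise ValueError(f"unknown config section {section!r}")
            sub = getattr(self, section)
            if key not in {f.name for f in dataclasses.fields(sub)}:
                raise ValueError(f"unknown key {key!r} in section {section!r}")
            return dataclasses.replace(self, **{section: dataclasses.replace(sub, **{key: value})})
        if dotted not in ("seed", "out_dir"):
            raise ValueError(f"unknown top-level config key {dotted!r}")
        return dataclasses.replace(self, **{dotted: value})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_snapshot(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)
        return path


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
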