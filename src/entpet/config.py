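"""Run configuration: one YAML-serialisable record of every knob and seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from entpet.classifier import ModelSpec, TrainSpec
from entpet.geometry import DetectorGeometry
from entpet.pipeline import EnergyWindow
from entpet.simulator import EnergyModel, SourceConfig
from entpet.workflow import DatasetSeeds

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    n_decays: int = 100_000
    n_samples: int = 10_000
    mode: str = "entangled"
    fraction_random: float = 0.5
    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    source: SourceConfig = field(default_factory=SourceConfig)
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    window: EnergyWindow = field(default_factory=EnergyWindow)
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainSpec = field(default_factory=TrainSpec)
    seeds: DatasetSeeds = field(default_factory=DatasetSeeds)
    folds: int = 5
    feature_subsets: list[list[str]] | None = None
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: enc(getattr(v, f.name))
                        for f in dataclasses.fields(v) if f.init}
            if isinstance(v, tuple):
                return list(v)
            if hasattr(v, "tolist"):
                return v.tolist()
            return v

        return enc(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


_TUPLE_FIELDS = {"encoder_widths", "fusion_widths", "crystal_size",
                 "array_shape", "position"}


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if not f.init or f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _build(f.type, v)
        kwargs[f.name] = tuple(v) if f.name in _TUPLE_FIELDS else v
    return cls(**kwargs)


_SUBCONFIGS = {
    "geometry": DetectorGeometry, "source": SourceConfig,
    "energy_model": EnergyModel, "window": EnergyWindow,
    "model": ModelSpec, "train": TrainSpec, "seeds": DatasetSeeds,
}


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for k, v in data.items():
        if k in _SUBCONFIGS:
            kwargs[k] = _build(_SUBCONFIGS[k], v)
        else:
            kwargs[k] = v
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
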