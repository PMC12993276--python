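"""Run configuration: one structured file covering every stage, with a
single global seed fanned out to per-stage seeds by stable hashing so stages
can be rerun independently yet reproducibly."""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .clustering import LossWeights, ScDMACConfig
from .masked_ae import MaskedAEConfig, MaskLossWeights
from .preprocessing import AugmentationConfig
from .simulate import SimulationConfig
from .zinb import DenoiserConfig


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "scdmac_out"
    verbosity: str = "info"
    n_clusters: int = 3
    pipeline: ScDMACConfig = field(default_factory=ScDMACConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        self.reseed(self.seed)

    def reseed(self, global_seed: int) -> None:
        """Fan the global seed out to every stage."""
        self.seed = int(global_seed)
        self.simulation.seed = derive_seed(global_seed, "simulate")
        self.pipeline.seed = derive_seed(global_seed, "cluster")
        self.pipeline.denoiser.seed = derive_seed(global_seed, "denoiser")
        self.pipeline.masked_ae.seed = derive_seed(global_seed, "masked_ae")
        self.pipeline.augmentation.seed = derive_seed(global_seed, "augment")


def _to_dict(obj):
    if is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        target = _NESTED.get((cls.__name__, name))
        if target is not None:
            kwargs[name] = _from_dict(target, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    ("RunConfig", "pipeline"): ScDMACConfig,
    ("RunConfig", "simulation"): SimulationConfig,
    ("ScDMACConfig", "denoiser"): DenoiserConfig,
    ("ScDMACConfig", "masked_ae"): MaskedAEConfig,
    ("ScDMACConfig", "loss_weights"): LossWeights,
    ("ScDMACConfig", "augmentation"): AugmentationConfig,
    ("MaskedAEConfig", "weights"): MaskLossWeights,
}


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    cfg = _from_dict(RunConfig, data)
    return cfg


def apply_overrides(cfg: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply dotted `--set key=value` overrides, e.g.
    `pipeline.masked_ae.mask_ratio=0.2`."""
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override must look like key=value: {item!r}")
        key, raw = item.split("=", 1)
        parts = key.split(".")
        target = cfg
        for part in parts[:-1]:
            if not hasattr(target, part):
                raise ValueError(f"unknown config path: {key!r}")
            target = getattr(target, part)
        leaf = parts[-1]
        if not hasattr(target, leaf):
            raise ValueError(f"unknown config path: {key!r}")
        current = getattr(target, leaf)
        value = yaml.safe_load(raw)
        if isinstance(current, tuple) and isinstance(value, list):
            value = tuple(value)
        setattr(target, leaf, value)
    return cfg
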