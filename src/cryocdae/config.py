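"""Run configuration and deterministic seed fan-out for the CLI workflow."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .autoencoder import BlockSpec, TrainConfig
from .metrics import EqualizeConfig
from .neighbors import NeighborConfig

__all__ = ["RunConfig", "SimulationConfig", "derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage-specific seed below 2**31: CRC32(stage) mixed with the global seed.

    Documented so each pipeline stage is independently reproducible from the
    single seed recorded in the manifest.
    """
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class SimulationConfig:
    side: int = 64
    n_components: int = 4
    n_per_class: int = 1000
    n_per_class_test: Optional[int] = None  # None: same as n_per_class
    snr_low: float = 0.1
    snr_mid: float = 0.4
    snr_high: float = 0.6
    orientations: Optional[list[list[float]]] = None  # None: 4 default views


@dataclass
class RunConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    block: BlockSpec = field(default_factory=BlockSpec)
    pretrain: TrainConfig = field(default_factory=TrainConfig)
    finetune: TrainConfig = field(default_factory=TrainConfig)
    neighbors: NeighborConfig = field(default_factory=NeighborConfig)
    equalize: EqualizeConfig = field(default_factory=EqualizeConfig)
    enhance: bool = True
    target_mode: str = "per_block"
    clustering_k: int = 4
    clustering_method: str = "kmeans"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        kwargs = {}
        for key, sub_cls in (
            ("simulation", SimulationConfig),
            ("block", BlockSpec),
            ("pretrain", TrainConfig),
            ("finetune", TrainConfig),
            ("neighbors", NeighborConfig),
            ("equalize", EqualizeConfig),
        ):
            if key in raw:
                kwargs[key] = sub_cls(**(raw.pop(key) or {}))
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
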