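"""Run configuration: nested YAML blocks with strict key checking.

A run config groups the per-stage blocks (io, filter, normalize, augment,
model, train, eval, simulate) with a global seed, log level and output
directory. Unknown keys are rejected rather than silently ignored, and
every pipeline run writes its resolved config next to its outputs so the
artifact is self-describing.

The single global seed fans out to per-stage seeds by stable hashing, so
repeated-run protocols (e.g. 5-repetition averaging) are reproducible
without per-stage bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augmentation import AugmentConfig
from .filters import FilterConfig
from .model import EncoderConfig
from .training import TrainConfig

KNOWN_BLOCKS = ("io", "filter", "normalize", "augment", "model", "train",
                "eval", "simulate")
KNOWN_TOP = KNOWN_BLOCKS + ("seed", "log_level", "output_dir")


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "runs"
    blocks: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(KNOWN_TOP)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        blocks = {k: d[k] for k in KNOWN_BLOCKS if k in d}
        return cls(seed=int(d.get("seed", 0)),
                   log_level=str(d.get("log_level", "INFO")),
                   output_dir=str(d.get("output_dir", "runs")),
                   blocks=blocks)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {"seed": self.seed, "log_level": self.log_level,
                "output_dir": self.output_dir, **self.blocks}

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def stage_seed(self, stage: str, repeat: int = 0) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}:{repeat}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)

    # typed accessors -------------------------------------------------------

    def filter_config(self) -> FilterConfig:
        return FilterConfig.from_dict(self.blocks.get("filter", {}))

    def augment_config(self) -> AugmentConfig:
        return AugmentConfig.from_dict(self.blocks.get("augment", {}))

    def encoder_config(self) -> EncoderConfig:
        block = dict(self.blocks.get("model", {}))
        if block.pop("small", False):
            return EncoderConfig.small()
        return EncoderConfig.from_dict(block) if block else EncoderConfig.small()

    def train_config(self, **overrides) -> TrainConfig:
        block = {**self.blocks.get("train", {}), **overrides}
        block.setdefault("seed", self.stage_seed("train"))
        return TrainConfig.from_dict(block)
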