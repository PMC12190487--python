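"""Run configuration: architecture switches plus training keys.

A run is reproducible from its config and seed alone.  Two profiles ship with
the package: ``desk`` (160-px input, width 0.25, 30 epochs) sized so that CPU
training finishes in minutes, and ``full`` (640-px input, batch 8, initial
learning rate 0.01, SGD, 130 epochs) recording the full-scale settings as
documentation defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ArchitectureConfig

__all__ = ["RunConfig", "PROFILES", "load_config", "save_config"]


@dataclass
class RunConfig:
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 0.01
    sgd_momentum: float = 0.9
    seed: int = 0
    flip_augment: bool = True
    conf_threshold: float = 0.25
    nms_iou: float = 0.5
    data_dir: str = "dataset"
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arch"] = asdict(self.arch)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        arch = ArchitectureConfig(**d.pop("arch", {}))
        return RunConfig(arch=arch, **d)


PROFILES: dict[str, RunConfig] = {
    "desk": RunConfig(
        arch=ArchitectureConfig(input_size=160, width_mult=0.25,
                                box_loss="ciou"),
        epochs=30, batch_size=8, learning_rate=0.03, seed=0),
    "full": RunConfig(
        arch=ArchitectureConfig(input_size=640, width_mult=0.25),
        epochs=130, batch_size=8, learning_rate=0.01, seed=0),
}


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
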