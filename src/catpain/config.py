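"""Pipeline configuration: one YAML tree controlling every stage.

All defaults are filled in at resolution time and echoed to the log, so
a run's provenance block plus the package version reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml

from catpain.alignment import AlignmentConfig
from catpain.augmentation import NoiseConfig
from catpain.errors import ConfigurationError
from catpain.model import TrainConfig
from catpain.synthetic_data import SynthConfig

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    align: bool = True
    augment: bool = True
    val_count: int = 6
    seed: int = 0
    alignment: AlignmentConfig = AlignmentConfig()
    noise: NoiseConfig = NoiseConfig()
    train: TrainConfig = TrainConfig()
    synth: SynthConfig = SynthConfig()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def provenance(self, package_version: str) -> dict:
        return {
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            "package_version": package_version,
        }


def _build(section: dict, cls, path: str):
    try:
        return cls(**section)
    except TypeError as exc:
        raise ConfigurationError(f"bad keys under {path!r}: {exc}") from exc


def load_config(path: Optional[str | Path] = None, **overrides) -> PipelineConfig:
    """Load a YAML config (missing keys fall back to defaults) and log it."""
    tree: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config root in {path} must be a mapping")
        tree = loaded
    tree.update(overrides)

    def tupled(section: dict, key: str) -> dict:
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
        return section

    config = PipelineConfig(
        align=bool(tree.get("align", True)),
        augment=bool(tree.get("augment", True)),
        val_count=int(tree.get("val_count", 6)),
        seed=int(tree.get("seed", 0)),
        alignment=_build(tree.get("alignment", {}), AlignmentConfig, "alignment"),
        noise=_build(tree.get("augmentation", {}), NoiseConfig, "augmentation"),
        train=_build(tree.get("train", {}), TrainConfig, "train"),
        synth=_build(
            tupled(tree.get("synth", {}), "scale_range"), SynthConfig, "synth"
        ),
    )
    logger.info("resolved config (hash %s): %s", config.config_hash(), config.to_dict())
    return config
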