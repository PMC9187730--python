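"""Noise-injection augmentation of feature tables.

New training samples are synthesized by multiplying every coordinate of
an original sample by an independent draw from a normal distribution
centered on 1 (default sd 0.0005), a perturbation small enough to keep
class geometry while regularizing the classifier.  Augmentation is only
ever applied to training rows; the evaluation module enforces that.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from catpain.errors import ValidationError
from catpain.features import FEATURE_COLUMNS


@dataclasses.dataclass(frozen=True)
class NoiseConfig:
    mean: float = 1.0
    sd: float = 0.0005
    copies_per_sample: int = 1
    seed: int = 0
    #: if True, one noise factor per row instead of one per coordinate
    per_sample_scalar: bool = False
    #: if True (default) fit() redraws noise each epoch; else a single draw
    resample_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if self.copies_per_sample < 0:
            raise ValidationError("copies_per_sample must be non-negative")


def draw_noise_factors(
    config: NoiseConfig, size: int | tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Sample the multiplicative noise factors: Normal(mean, sd)."""
    return rng.normal(loc=config.mean, scale=config.sd, size=size)


def augment(
    features: pd.DataFrame,
    config: NoiseConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Return originals plus ``copies_per_sample`` noisy copies of each row.

    Copies multiply each feature element by an independent noise factor
    (or one factor per row when ``per_sample_scalar``); metadata columns
    are carried over and copies are flagged in an ``augmented`` column.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature table contains non-finite values")

    out = features.copy()
    out["augmented"] = False
    if config.copies_per_sample == 0 or len(features) == 0:
        return out.reset_index(drop=True)

    pieces = [out]
    n = len(features)
    for copy_idx in range(config.copies_per_sample):
        if config.per_sample_scalar:
            factors = draw_noise_factors(config, (n, 1), rng)
        else:
            factors = draw_noise_factors(config, X.shape, rng)
        noisy = features.copy()
        noisy[list(FEATURE_COLUMNS)] = X * factors
        noisy["sample_id"] = [
            f"{sid}__aug{copy_idx + 1}" for sid in features["sample_id"]
        ]
        noisy["augmented"] = True
        pieces.append(noisy)
    return pd.concat(pieces, ignore_index=True)
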