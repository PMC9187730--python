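"""Synthetic landmark datasets with the structure the pipeline assumes.

Real surgical footage cannot ship with the package, so tests and demos
run on generated data that reproduces the statistical skeleton of a
peri-operative cat-face study: a fixed 48-landmark template face,
a pain deformation field motivated by grimace-scale features (narrowed
eyes, flattened/rotated ears, tightened muzzle), persistent per-subject
shape idiosyncrasy, per-image annotation jitter, and nuisance pose
(rotation / scale / translation of the whole landmark set).

Subject idiosyncrasy is additive and class-independent, so the only
class signal is the deformation field: at ``effect_size = 0`` the classes
are exchangeable by construction and chance-level classification is a
designed ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from catpain.data_model import (
    LandmarkSet,
    Manifest,
    N_LANDMARKS,
    Sample,
    Timepoint,
    assign_labels,
)
from catpain.errors import ValidationError

#: Template face, version 1: nominal 500x500 frame, y down, midline x=250.
#: Landmark roles follow the region scheme: 37/38 and 41/42 are eye
#: corners (midpoints = eye centers, level and symmetric about the
#: midline), 17 is the nose tip, 27/28 flank the forehead center,
#: 23-26 / 29-32 trace the ears, the rest cover lids, muzzle and jaw.
TEMPLATE_VERSION = 1
_TEMPLATE_POINTS: dict[int, tuple[float, float]] = {
    # left cheek / right cheek
    1: (110.0, 230.0), 3: (390.0, 230.0),
    # left eye: corners 37/38, lids 4-8, lower lid 39
    37: (148.0, 200.0), 38: (192.0, 200.0),
    4: (148.0, 182.0), 5: (170.0, 174.0), 6: (192.0, 182.0),
    7: (196.0, 212.0), 8: (144.0, 212.0), 39: (170.0, 222.0),
    # right eye: corners 41/42, lids 9-12 and 2, lower lid 40
    41: (308.0, 200.0), 42: (352.0, 200.0),
    9: (308.0, 182.0), 10: (330.0, 174.0), 11: (352.0, 182.0),
    12: (356.0, 212.0), 2: (304.0, 212.0), 40: (330.0, 222.0),
    # forehead / ears: 23-26 left ear, 27/28 brow, 29-32 right ear
    23: (120.0, 60.0), 24: (150.0, 30.0), 25: (180.0, 80.0), 26: (205.0, 110.0),
    27: (230.0, 120.0), 28: (270.0, 120.0),
    29: (295.0, 110.0), 30: (320.0, 80.0), 31: (350.0, 30.0), 32: (380.0, 60.0),
    # nose / nostrils
    17: (250.0, 300.0), 48: (250.0, 270.0),
    43: (230.0, 290.0), 44: (270.0, 290.0),
    45: (235.0, 315.0), 46: (265.0, 315.0), 47: (250.0, 330.0),
    # whisker pads
    18: (170.0, 300.0), 19: (160.0, 330.0), 20: (185.0, 345.0),
    21: (330.0, 300.0), 22: (340.0, 330.0),
    # mouth and chin/jaw
    13: (200.0, 350.0), 14: (250.0, 365.0), 15: (300.0, 350.0), 16: (250.0, 345.0),
    33: (210.0, 390.0), 34: (250.0, 400.0), 35: (290.0, 390.0), 36: (250.0, 380.0),
}

_MIDLINE_X = 250.0


def make_template() -> LandmarkSet:
    """The canonical synthetic cat face (frozen, versioned fixture)."""
    coords = np.array([_TEMPLATE_POINTS[i] for i in range(1, N_LANDMARKS + 1)])
    return LandmarkSet(coords)


def _deformation_field() -> np.ndarray:
    """Unit pain-deformation field (48x2): 1 px displacement per unit effect.

    Eye-region landmarks move toward their eye center (lid narrowing),
    forehead/ear landmarks drift laterally and downward (ear flattening),
    muzzle landmarks tighten toward the nose tip.
    """
    template = make_template()
    field = np.zeros((N_LANDMARKS, 2))
    left_center = template.midpoint(37, 38)
    right_center = template.midpoint(41, 42)
    nose = template.point(17)

    def unit_toward(point: np.ndarray, target: np.ndarray) -> np.ndarray:
        d = target - point
        norm = float(np.hypot(*d))
        return d / norm if norm > 1e-9 else np.zeros(2)

    for lid in (4, 5, 6, 7, 8, 37, 38, 39):
        field[lid - 1] = unit_toward(template.point(lid), left_center)
    for lid in (2, 9, 10, 11, 12, 40, 41, 42):
        field[lid - 1] = unit_toward(template.point(lid), right_center)
    for lid in range(23, 33):
        x = template.point(lid)[0]
        lateral = math.copysign(0.6, x - _MIDLINE_X)
        field[lid - 1] = np.array([lateral, 0.8])
    for lid in (1, 3, 13, 14, 15, 16, 18, 19, 20, 21, 22,
                33, 34, 35, 36, 43, 44, 45, 46, 47, 48):
        field[lid - 1] = unit_toward(template.point(lid), nose)
    return field


PAIN_FIELD = _deformation_field()


def pain_deformation(template: LandmarkSet, effect_size: float) -> LandmarkSet:
    """Template displaced by ``effect_size`` times the unit pain field (linear)."""
    if effect_size < 0:
        raise ValidationError("effect_size must be non-negative")
    return LandmarkSet(template.coords + effect_size * PAIN_FIELD)


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults mirror the canonical study layout.

    26 subjects x 9 images per class gives 468 balanced samples, close to
    the 464 of the motivating dataset.  ``single_class_subjects`` adds
    subjects carrying only one class, to exercise the completeness filter.
    """

    n_subjects: int = 26
    images_per_subject_per_class: int = 9
    effect_size: float = 3.0
    subject_sd: float = 2.0
    obs_sd: float = 1.0
    max_rotation_deg: float = 25.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    max_translation: float = 50.0
    single_class_subjects: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.images_per_subject_per_class) < 0:
            raise ValidationError("counts must be non-negative")
        if self.single_class_subjects < 0 or self.single_class_subjects > self.n_subjects:
            raise ValidationError("single_class_subjects must be within 0..n_subjects")
        if self.effect_size < 0 or self.subject_sd < 0 or self.obs_sd < 0:
            raise ValidationError("effect_size and noise scales must be non-negative")
        if not 0 < self.scale_range[0] <= self.scale_range[1]:
            raise ValidationError("scale_range must be positive and ordered")


def _random_pose(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[float, float, np.ndarray]:
    angle = math.radians(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
    scale = rng.uniform(*config.scale_range)
    translation = rng.uniform(-config.max_translation, config.max_translation, size=2)
    return angle, scale, translation


def _apply_pose(
    coords: np.ndarray, angle: float, scale: float, translation: np.ndarray
) -> np.ndarray:
    center = np.array([_MIDLINE_X, _MIDLINE_X])  # template frame center
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return (coords - center) @ (scale * rot).T + center + translation


#: timepoints cycled through for no-pain images
_NO_PAIN_TIMEPOINTS = (Timepoint.PRE_SURGERY, Timepoint.POST_RESCUE)


def generate(config: SynthConfig = SynthConfig()) -> Manifest:
    """Generate a labeled synthetic manifest.

    Per subject: one persistent Normal(0, subject_sd) offset field; per
    image: template (+ pain deformation for pain-class images) + subject
    offset + Normal(0, obs_sd) jitter, then a random similarity pose.
    The first ``single_class_subjects`` subjects alternate between
    pain-only and no-pain-only; all others get both classes.
    """
    rng = np.random.default_rng(config.seed)
    template = make_template()
    pain_face = pain_deformation(template, config.effect_size)
    width = len(str(max(config.n_subjects, 1)))

    samples: list[Sample] = []
    for si in range(config.n_subjects):
        subject_id = f"cat{si + 1:0{width}d}"
        subject_offset = rng.normal(0.0, config.subject_sd, size=(N_LANDMARKS, 2))
        if si < config.single_class_subjects:
            classes = ["pain"] if si % 2 == 0 else ["no_pain"]
        else:
            classes = ["no_pain", "pain"]
        for cls in classes:
            base = pain_face if cls == "pain" else template
            for k in range(config.images_per_subject_per_class):
                if cls == "pain":
                    timepoint = Timepoint.POST_SURGERY_1H
                else:
                    timepoint = _NO_PAIN_TIMEPOINTS[k % 2]
                coords = (
                    base.coords
                    + subject_offset
                    + rng.normal(0.0, config.obs_sd, size=(N_LANDMARKS, 2))
                )
                coords = _apply_pose(coords, *_random_pose(config, rng))
                samples.append(
                    Sample(
                        sample_id=f"{subject_id}_{timepoint.value}_{k:02d}",
                        subject_id=subject_id,
                        timepoint=timepoint,
                        landmarks=LandmarkSet(coords),
                    )
                )
    manifest = Manifest(
        samples,
        provenance={
            "generator": "catpain.synthetic_data",
            "template_version": TEMPLATE_VERSION,
            "config": dataclasses.asdict(config),
        },
    )
    return assign_labels(manifest)


def render_face(
    landmarks: LandmarkSet,
    width: int = 500,
    height: int = 500,
    dot_radius: int = 2,
) -> np.ndarray:
    """Schematic raster: white dots at landmark positions on black.

    Only for exercising image warping; not a photorealistic face.
    """
    img = np.zeros((height, width), dtype=np.uint8)
    yy, xx = np.mgrid[0:height, 0:width]
    for x, y in landmarks.coords:
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= dot_radius**2
        img[mask] = 255
    return img
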