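"""Eye-anchored similarity alignment of cat faces.

Each face is mapped into a canonical output frame (default 1000x1000 px)
by a similarity transform — rotation, isotropic scale and translation —
determined entirely by the two eye centers:

* the left-eye center (midpoint of landmarks 37 and 38) lands at
  ``(f*W, f*H)`` with anchor fraction ``f = 0.4``;
* the right-eye center (midpoint of landmarks 41 and 42) lands
  equidistant from the right edge, i.e. at ``((1-f)*W, f*H)``;
* consequently the eye line is horizontal and the inter-eye distance is
  ``(1 - 2f)*W`` in every aligned face.

"Left" and "right" refer to landmark IDs, not anatomical laterality; only
consistency across the dataset matters.  Landmarks can be aligned with no
raster present; :func:`apply_to_image` warps pixels with the same
transform when images are available.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np

from catpain.data_model import LandmarkSet, Manifest, Sample
from catpain.errors import DegenerateGeometryError, ValidationError

LEFT_EYE_PAIR = (37, 38)
RIGHT_EYE_PAIR = (41, 42)


@dataclasses.dataclass(frozen=True)
class AlignmentConfig:
    out_width: int = 1000
    out_height: int = 1000
    eye_anchor_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.out_width <= 0 or self.out_height <= 0:
            raise ValidationError("output dimensions must be positive")
        if not 0.0 < self.eye_anchor_fraction < 0.5:
            raise ValidationError("eye_anchor_fraction must lie in (0, 0.5)")

    @property
    def left_eye_target(self) -> np.ndarray:
        f = self.eye_anchor_fraction
        return np.array([f * self.out_width, f * self.out_height])

    @property
    def right_eye_target(self) -> np.ndarray:
        f = self.eye_anchor_fraction
        return np.array([(1.0 - f) * self.out_width, f * self.out_height])

    @property
    def target_inter_eye_distance(self) -> float:
        return (1.0 - 2.0 * self.eye_anchor_fraction) * self.out_width


@dataclasses.dataclass(frozen=True)
class SimilarityTransform:
    """p' = s * R(angle) @ p + t, in the y-down pixel convention.

    ``angle`` is the rotation applied by the transform; a face whose eye
    line rises to the right (negative screen slope in y-down coordinates)
    is corrected by the opposite rotation.
    """

    angle: float
    scale: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError("similarity scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """2x3 affine matrix [s*R | t]."""
        c, s = math.cos(self.angle), math.sin(self.angle)
        a = self.scale
        return np.array(
            [
                [a * c, -a * s, self.translation[0]],
                [a * s, a * c, self.translation[1]],
            ]
        )

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "SimilarityTransform":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValidationError(f"expected a 2x3 affine matrix, got {m.shape}")
        a = np.hypot(m[0, 0], m[1, 0])
        if not a > 0:
            raise ValidationError("matrix has non-positive scale")
        # similarity consistency: columns orthogonal, equal norm
        if not (
            np.isclose(np.hypot(m[0, 1], m[1, 1]), a, rtol=1e-9, atol=1e-12)
            and np.isclose(m[0, 0], m[1, 1], rtol=1e-9, atol=1e-12)
            and np.isclose(m[0, 1], -m[1, 0], rtol=1e-9, atol=1e-12)
        ):
            raise ValidationError("matrix is not rotation*scale + translation")
        angle = math.atan2(m[1, 0], m[0, 0])
        return cls(angle=angle, scale=float(a), translation=(float(m[0, 2]), float(m[1, 2])))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(angle=0.0, scale=1.0, translation=(0.0, 0.0))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        return pts @ m[:, :2].T + m[:, 2]

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.angle), math.sin(-self.angle)
        tx, ty = self.translation
        return SimilarityTransform(
            angle=-self.angle,
            scale=inv_scale,
            translation=(
                -inv_scale * (c * tx - s * ty),
                -inv_scale * (s * tx + c * ty),
            ),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "angle": self.angle,
                "scale": self.scale,
                "tx": self.translation[0],
                "ty": self.translation[1],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "SimilarityTransform":
        d = json.loads(payload)
        return cls(angle=d["angle"], scale=d["scale"], translation=(d["tx"], d["ty"]))


def eye_centers(landmarks: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Left and right eye centers: midpoints of landmark pairs 37/38 and 41/42."""
    return landmarks.midpoint(*LEFT_EYE_PAIR), landmarks.midpoint(*RIGHT_EYE_PAIR)


def compute_transform(
    landmarks: LandmarkSet, config: AlignmentConfig = AlignmentConfig()
) -> SimilarityTransform:
    """Solve the similarity transform carrying both eye centers to their anchors.

    Rotation brings the eye line horizontal; scale sets the inter-eye
    distance to ``(1 - 2f)*W``; the eye midpoint translates to
    ``(0.5*W, f*H)``.
    """
    left, right = eye_centers(landmarks)
    delta = right - left
    dist = float(np.hypot(*delta))
    if dist < 1e-12:
        raise DegenerateGeometryError(
            "coincident eye centers: inter-eye distance is zero, scale undefined"
        )
    scale = config.target_inter_eye_distance / dist
    # rotate by -theta so the left->right eye direction maps onto +x
    theta = math.atan2(delta[1], delta[0])
    angle = -theta
    mid = (left + right) / 2.0
    target_mid = (config.left_eye_target + config.right_eye_target) / 2.0
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    translation = target_mid - scale * rot @ mid
    return SimilarityTransform(
        angle=angle, scale=scale, translation=(float(translation[0]), float(translation[1]))
    )


def apply_to_landmarks(
    transform: SimilarityTransform, landmarks: LandmarkSet
) -> LandmarkSet:
    return LandmarkSet(transform.apply(landmarks.coords))


def align_landmarks(
    landmarks: LandmarkSet, config: AlignmentConfig = AlignmentConfig()
) -> LandmarkSet:
    """Convenience: compute the eye-anchored transform and apply it."""
    return apply_to_landmarks(compute_transform(landmarks, config), landmarks)


def align_manifest(
    manifest: Manifest, config: AlignmentConfig = AlignmentConfig()
) -> Manifest:
    """Align every sample's landmarks (landmark-only mode; rasters untouched)."""
    samples = [
        s.with_landmarks(align_landmarks(s.landmarks, config)) for s in manifest.samples
    ]
    provenance = dict(manifest.provenance)
    provenance["aligned"] = {
        "out_width": config.out_width,
        "out_height": config.out_height,
        "eye_anchor_fraction": config.eye_anchor_fraction,
    }
    return Manifest(samples, provenance=provenance)


def apply_to_image(
    transform: SimilarityTransform,
    image: np.ndarray,
    config: AlignmentConfig = AlignmentConfig(),
) -> np.ndarray:
    """Warp a raster with the transform into the canonical output frame.

    Bilinear resampling; pixels with no source fall to black.  The output
    is exactly ``out_height x out_width`` (gray or multi-channel following
    the input).
    """
    from skimage.transform import AffineTransform, warp

    img = np.asarray(image)
    # skimage transforms act on (x, y) = (col, row) coordinates, same
    # convention as the landmark frame, so the matrix carries over directly.
    fwd = AffineTransform(matrix=np.vstack([transform.matrix, [0.0, 0.0, 1.0]]))
    out_shape = (config.out_height, config.out_width) + img.shape[2:]
    warped = warp(
        img,
        inverse_map=fwd.inverse,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    return warped.astype(img.dtype) if np.issubdtype(img.dtype, np.floating) else warped


def read_image(path: str | Path) -> np.ndarray:
    from skimage.io import imread

    try:
        return imread(Path(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # pillow raises various decode errors
        raise OSError(f"unreadable image {path}: {exc}") from exc


def align_sample_image(
    sample: Sample, config: AlignmentConfig = AlignmentConfig()
) -> Optional[np.ndarray]:
    """Warp a sample's raster, if it has one, with the sample's own transform."""
    if sample.image_path is None:
        return None
    transform = compute_transform(sample.landmarks, config)
    return apply_to_image(transform, read_image(sample.image_path), config)
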