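"""Multi-region vectorization of aligned landmarks.

Four grimace-scale-derived face regions partition the 48 landmarks:
left eye (8), right eye (8), nose/mouth/whiskers (22) and forehead (10).
Each landmark is expressed as its offset from the center of its region
(eye centers are eye-corner midpoints, the nose region centers on the
nose-tip landmark 17, the forehead on the midpoint of landmarks 27/28).
Concatenated in landmark-ID order, x before y, the offsets form the
96-dimensional multi-region vector fed to the classifier.

Only per-region translation is removed here; rotation and scale are the
alignment module's job, performed upstream in the pipeline.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from catpain.data_model import Label, LandmarkSet, Manifest, N_LANDMARKS
from catpain.errors import ValidationError

N_FEATURES = 2 * N_LANDMARKS
FEATURE_COLUMNS: tuple[str, ...] = tuple(f"f{i}" for i in range(1, N_FEATURES + 1))
META_FEATURE_COLUMNS = ("sample_id", "subject_id", "label")


@dataclasses.dataclass(frozen=True)
class RegionScheme:
    """Named regions with member landmark IDs and center rules.

    ``centers`` maps a region name either to a pair of landmark IDs
    (center = their midpoint) or a single ID (center = that landmark).
    """

    members: Mapping[str, frozenset[int]]
    centers: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        all_ids: list[int] = []
        for name, ids in self.members.items():
            if name not in self.centers:
                raise ValidationError(f"region {name!r} has no center rule")
            all_ids.extend(ids)
        if sorted(all_ids) != list(range(1, N_LANDMARKS + 1)):
            raise ValidationError(
                "region member sets must partition landmark IDs 1..48 "
                "(disjoint, none missing)"
            )

    def region_of(self, landmark_id: int) -> str:
        for name, ids in self.members.items():
            if landmark_id in ids:
                return name
        raise ValidationError(f"landmark {landmark_id} not in any region")

    def center(self, name: str, landmarks: LandmarkSet) -> np.ndarray:
        rule = self.centers[name]
        if len(rule) == 1:
            return landmarks.point(rule[0]).copy()
        if len(rule) == 2:
            return landmarks.midpoint(*rule)
        raise ValidationError(f"center rule for {name!r} must name 1 or 2 landmarks")


#: The grimace-scale region scheme (sizes 8 / 8 / 22 / 10).
DEFAULT_SCHEME = RegionScheme(
    members={
        "left_eye": frozenset({4, 5, 6, 7, 8, 37, 38, 39}),
        "right_eye": frozenset({2, 9, 10, 11, 12, 40, 41, 42}),
        "nose_mouth_whiskers": frozenset(
            {1, 3, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22,
             33, 34, 35, 36, 43, 44, 45, 46, 47, 48}
        ),
        "forehead": frozenset({23, 24, 25, 26, 27, 28, 29, 30, 31, 32}),
    },
    centers={
        "left_eye": (37, 38),
        "right_eye": (41, 42),
        "nose_mouth_whiskers": (17,),
        "forehead": (27, 28),
    },
)

# 0-based landmark index -> region name, resolved once at import.
_REGION_BY_INDEX: tuple[str, ...] = tuple(
    DEFAULT_SCHEME.region_of(i + 1) for i in range(N_LANDMARKS)
)


def region_centers(
    landmarks: LandmarkSet, scheme: RegionScheme = DEFAULT_SCHEME
) -> dict[str, np.ndarray]:
    """Center point of each region for this face."""
    return {name: scheme.center(name, landmarks) for name in scheme.members}


def vectorize(
    landmarks: LandmarkSet, scheme: RegionScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """96-element multi-region vector: per-landmark offsets from region centers."""
    centers = region_centers(landmarks, scheme)
    if scheme is DEFAULT_SCHEME:
        center_rows = np.array([centers[_REGION_BY_INDEX[i]] for i in range(N_LANDMARKS)])
    else:
        center_rows = np.array(
            [centers[scheme.region_of(i + 1)] for i in range(N_LANDMARKS)]
        )
    return (landmarks.coords - center_rows).reshape(-1)


def devectorize(
    vector: np.ndarray,
    centers: Mapping[str, np.ndarray],
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> LandmarkSet:
    """Invert :func:`vectorize` given the four region centers."""
    offsets = np.asarray(vector, dtype=float).reshape(N_LANDMARKS, 2)
    center_rows = np.array(
        [centers[scheme.region_of(i + 1)] for i in range(N_LANDMARKS)]
    )
    return LandmarkSet(offsets + center_rows)


def _looks_aligned(landmarks: LandmarkSet, tol: float = 1e-6) -> bool:
    left = landmarks.midpoint(37, 38)
    right = landmarks.midpoint(41, 42)
    return abs(float(left[1] - right[1])) < tol


def build_feature_matrix(
    manifest: Manifest,
    scheme: RegionScheme = DEFAULT_SCHEME,
    on_unaligned: str = "warn",
) -> pd.DataFrame:
    """Vectorize every sample into an n x 96 table with carried metadata.

    Rows are ordered by ``sample_id`` for determinism.  Faces whose eye
    line is not horizontal have evidently not been through alignment;
    depending on ``on_unaligned`` this warns (default), raises, or is
    ignored (``"ignore"``, used when alignment is deliberately disabled).
    """
    if on_unaligned not in ("warn", "reject", "ignore"):
        raise ValidationError("on_unaligned must be 'warn', 'reject' or 'ignore'")
    records = []
    for sample in sorted(manifest.samples, key=lambda s: s.sample_id):
        if on_unaligned != "ignore" and not _looks_aligned(sample.landmarks):
            msg = f"sample {sample.sample_id} does not look aligned (eye line not horizontal)"
            if on_unaligned == "reject":
                raise ValidationError(msg)
            warnings.warn(msg)
        row: dict = {
            "sample_id": sample.sample_id,
            "subject_id": sample.subject_id,
            "label": sample.label.value if sample.label is not None else None,
        }
        row.update(zip(FEATURE_COLUMNS, vectorize(sample.landmarks, scheme)))
        records.append(row)
    columns = list(META_FEATURE_COLUMNS) + list(FEATURE_COLUMNS)
    if not records:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame.from_records(records, columns=columns)
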