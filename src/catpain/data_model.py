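"""Samples, manifests, pain-label assignment and the subject filter.

A *sample* is one annotated cat-face image: 48 two-dimensional landmarks
in pixel coordinates (x right, y down from the upper-left corner), a
subject (cat) identifier, and the recording timepoint relative to
ovariohysterectomy.  Pain labels are a pure function of the timepoint:
images taken one hour after surgery (before rescue analgesia) are
``pain``; pre-surgery and post-rescue images are ``no_pain``.

Subjects contributing only a single label class are uninformative for
subject-exclusive evaluation and are removed wholesale by
:func:`filter_complete_subjects`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from catpain.errors import ParseError, SchemaError, ValidationError

N_LANDMARKS = 48

#: CSV columns holding the coordinates, in landmark-ID order: x1,y1,...,x48,y48.
COORD_COLUMNS: tuple[str, ...] = tuple(
    c for i in range(1, N_LANDMARKS + 1) for c in (f"x{i}", f"y{i}")
)
META_COLUMNS = ("sample_id", "subject_id", "timepoint")


class Timepoint(str, enum.Enum):
    PRE_SURGERY = "pre_surgery"
    POST_SURGERY_1H = "post_surgery_1h"
    POST_RESCUE = "post_rescue"


class Label(str, enum.Enum):
    NO_PAIN = "no_pain"
    PAIN = "pain"


#: Label assignment rule: only the 1h-post-surgery timepoint is painful.
LABEL_BY_TIMEPOINT: Mapping[Timepoint, Label] = {
    Timepoint.PRE_SURGERY: Label.NO_PAIN,
    Timepoint.POST_SURGERY_1H: Label.PAIN,
    Timepoint.POST_RESCUE: Label.NO_PAIN,
}


@dataclasses.dataclass(frozen=True)
class LandmarkSet:
    """Ordered set of 48 (x, y) landmarks; IDs are 1-based externally.

    Internally coordinates live in a ``(48, 2)`` float array indexed
    0-based; :meth:`point` is the single boundary where 1-based landmark
    IDs are translated.
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"expected {N_LANDMARKS} landmarks with 2 coordinates each, "
                f"got array of shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("landmark coordinates must be finite")
        object.__setattr__(self, "coords", arr)

    def point(self, landmark_id: int) -> np.ndarray:
        """Coordinate pair for a 1-based landmark ID."""
        if not 1 <= landmark_id <= N_LANDMARKS:
            raise ValidationError(f"landmark ID {landmark_id} outside 1..{N_LANDMARKS}")
        return self.coords[landmark_id - 1]

    def midpoint(self, id_a: int, id_b: int) -> np.ndarray:
        return (self.point(id_a) + self.point(id_b)) / 2.0

    def as_flat(self) -> np.ndarray:
        """Coordinates flattened to (x1, y1, ..., x48, y48)."""
        return self.coords.reshape(-1)

    @classmethod
    def from_flat(cls, values: Sequence[float]) -> "LandmarkSet":
        arr = np.asarray(values, dtype=float)
        if arr.size != 2 * N_LANDMARKS:
            raise ValidationError(
                f"expected {2 * N_LANDMARKS} coordinate values, got {arr.size}"
            )
        return cls(arr.reshape(N_LANDMARKS, 2))


@dataclasses.dataclass(frozen=True)
class Sample:
    sample_id: str
    subject_id: str
    timepoint: Timepoint
    landmarks: LandmarkSet
    label: Optional[Label] = None
    image_path: Optional[Path] = None

    def with_label(self, label: Label) -> "Sample":
        return dataclasses.replace(self, label=label)

    def with_landmarks(self, landmarks: LandmarkSet) -> "Sample":
        return dataclasses.replace(self, landmarks=landmarks)


@dataclasses.dataclass
class Manifest:
    """A collection of samples plus provenance metadata (source, filter log)."""

    samples: list[Sample]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def subjects(self) -> list[str]:
        """Distinct subject IDs in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    def subset(self, sample_ids: Iterable[str]) -> "Manifest":
        wanted = set(sample_ids)
        return Manifest(
            [s for s in self.samples if s.sample_id in wanted],
            provenance=dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row: dict = {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "timepoint": s.timepoint.value,
            }
            if s.label is not None:
                row["label"] = s.label.value
            if s.image_path is not None:
                row["image_path"] = str(s.image_path)
            row.update(zip(COORD_COLUMNS, s.landmarks.as_flat()))
            rows.append(row)
        return pd.DataFrame(rows)


# Column-name dialects: map canonical names to alternatives found in the wild.
DEFAULT_DIALECT: Mapping[str, str] = {}


def _resolve_columns(columns: Sequence[str], dialect: Mapping[str, str]) -> dict[str, str]:
    """Map canonical column names to the file's actual names via the dialect."""
    mapping = {}
    for canonical in (*META_COLUMNS, *COORD_COLUMNS, "label", "image_path"):
        actual = dialect.get(canonical, canonical)
        if actual in columns:
            mapping[canonical] = actual
    return mapping


def load_manifest(path: str | Path, dialect: Optional[Mapping[str, str]] = None) -> Manifest:
    """Read a delimited-text manifest: one row per sample, 96 coordinate columns.

    ``dialect`` maps canonical column names (``sample_id``, ``x1`` ...) to
    the file's actual headers, so alternative layouts load without edits.
    Labels are parsed only if a label column is present; otherwise they are
    assigned later from timepoints by :func:`assign_labels`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    colmap = _resolve_columns(df.columns, dialect or DEFAULT_DIALECT)

    missing_meta = [c for c in META_COLUMNS if c not in colmap]
    if missing_meta:
        raise SchemaError(f"manifest {path} missing required columns: {missing_meta}")
    missing_coords = [c for c in COORD_COLUMNS if c not in colmap]
    if missing_coords:
        raise SchemaError(
            f"manifest {path} missing coordinate columns: {missing_coords}"
        )

    coord_cols = [colmap[c] for c in COORD_COLUMNS]
    try:
        coords = df[coord_cols].astype(float).to_numpy()
    except (TypeError, ValueError):
        for ridx in range(len(df)):
            try:
                df.loc[df.index[ridx], coord_cols].astype(float)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"non-numeric coordinate in row {ridx} of {path}: {exc}"
                ) from exc
        raise  # pragma: no cover - unreachable: some row must have failed

    samples = []
    for ridx, (_, row) in enumerate(df.iterrows()):
        tp_raw = str(row[colmap["timepoint"]])
        try:
            tp = Timepoint(tp_raw)
        except ValueError as exc:
            raise ValidationError(
                f"unknown timepoint {tp_raw!r} in row {ridx} of {path}"
            ) from exc
        label = None
        if "label" in colmap and not pd.isna(row[colmap["label"]]):
            try:
                label = Label(str(row[colmap["label"]]))
            except ValueError as exc:
                raise ValidationError(
                    f"unknown label {row[colmap['label']]!r} in row {ridx} of {path}"
                ) from exc
        image_path = None
        if "image_path" in colmap and not pd.isna(row[colmap["image_path"]]):
            image_path = Path(str(row[colmap["image_path"]]))
        samples.append(
            Sample(
                sample_id=str(row[colmap["sample_id"]]),
                subject_id=str(row[colmap["subject_id"]]),
                timepoint=tp,
                landmarks=LandmarkSet.from_flat(coords[ridx]),
                label=label,
                image_path=image_path,
            )
        )
    return Manifest(samples, provenance={"source": str(path)})


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write the canonical CSV schema; provenance goes to a sibling JSON file."""
    path = Path(path)
    manifest.to_frame().to_csv(path, index=False)
    if manifest.provenance:
        path.with_suffix(".provenance.json").write_text(
            json.dumps(manifest.provenance, indent=2, default=str)
        )


def assign_labels(manifest: Manifest) -> Manifest:
    """Derive pain labels from timepoints (post-surgery-1h is the pain class)."""
    samples = [s.with_label(LABEL_BY_TIMEPOINT[s.timepoint]) for s in manifest.samples]
    return Manifest(samples, provenance=dict(manifest.provenance))


def filter_complete_subjects(manifest: Manifest) -> Manifest:
    """Drop every sample of subjects that carry only one label class.

    Mirrors the study-design step of discarding cats for which only pain
    or only no-pain images exist.  The discarded subject IDs are recorded
    in ``provenance["discarded_subjects"]``.
    """
    if not manifest.samples:
        warnings.warn("filter_complete_subjects called on an empty manifest")
        return Manifest([], provenance=dict(manifest.provenance))
    if any(s.label is None for s in manifest.samples):
        raise ValidationError("labels must be assigned before filtering subjects")

    labels_by_subject: dict[str, set[Label]] = {}
    for s in manifest.samples:
        labels_by_subject.setdefault(s.subject_id, set()).add(s.label)
    discarded = sorted(
        subj for subj, labels in labels_by_subject.items() if len(labels) < 2
    )
    kept = [s for s in manifest.samples if s.subject_id not in set(discarded)]
    provenance = dict(manifest.provenance)
    provenance["discarded_subjects"] = discarded
    return Manifest(kept, provenance=provenance)


def balance_classes(manifest: Manifest, seed: int) -> Manifest:
    """Optionally subsample the majority class to equal class counts.

    The source study balanced its 232/232 images by selection; this rule
    is a configurable stand-in, not part of the mandatory filter.
    """
    if any(s.label is None for s in manifest.samples):
        raise ValidationError("labels must be assigned before balancing")
    by_label: dict[Label, list[Sample]] = {Label.NO_PAIN: [], Label.PAIN: []}
    for s in manifest.samples:
        by_label[s.label].append(s)
    n_min = min(len(v) for v in by_label.values())
    rng = np.random.default_rng(seed)
    keep_ids: set[str] = set()
    for samples in by_label.values():
        idx = rng.choice(len(samples), size=n_min, replace=False)
        keep_ids.update(samples[i].sample_id for i in idx)
    kept = [s for s in manifest.samples if s.sample_id in keep_ids]
    provenance = dict(manifest.provenance)
    provenance["balanced_to_per_class"] = n_min
    return Manifest(kept, provenance=provenance)
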