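"""Subject-exclusive leave-one-subject-out evaluation.

Each cat serves exactly once as the sole test subject; a fixed number of
validation subjects (default 6) is drawn from the remainder and the rest
train — 19/6/1 for the canonical 26-subject dataset.  Keeping every
individual's images inside a single partition forces the classifier to
generalize to unseen cats rather than memorizing subject identity.

Per-fold test metrics use the standard confusion-matrix conventions with
``pain`` as the positive class:

    accuracy  = (TP + TN) / total
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

Aggregates are the unweighted mean and sample standard deviation (ddof 1)
across folds; pooled-confusion variants are reported alongside.  Folds
where a metric's denominator is zero are excluded from that metric's
aggregate, with a logged count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from catpain.alignment import AlignmentConfig, align_manifest
from catpain.augmentation import NoiseConfig
from catpain.data_model import Label, Manifest
from catpain.errors import ConfigurationError, ValidationError
from catpain.features import build_feature_matrix
from catpain.model import TrainConfig, fit, predict

logger = logging.getLogger(__name__)

POSITIVE_CLASS = Label.PAIN.value


@dataclasses.dataclass(frozen=True)
class Fold:
    train_subjects: frozenset[str]
    val_subjects: frozenset[str]
    test_subject: str

    def check_disjoint(self, all_subjects: frozenset[str]) -> None:
        test = frozenset({self.test_subject})
        if (
            self.train_subjects & self.val_subjects
            or self.train_subjects & test
            or self.val_subjects & test
        ):
            raise ValidationError("fold partitions overlap")
        if self.train_subjects | self.val_subjects | test != all_subjects:
            raise ValidationError("fold partitions do not cover all subjects")


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    folds: tuple[Fold, ...]
    val_count: int
    seed: int


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclasses.dataclass(frozen=True)
class MetricValues:
    """Accuracy/precision/recall; a metric is None when its denominator is 0."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]


def make_loso_folds(
    subjects: Sequence[str], val_count: int = 6, seed: int = 0
) -> FoldPlan:
    """One fold per subject as test; validation drawn seeded from the rest.

    The validation subjects of fold ``i`` are drawn with a per-fold seed
    ``seed + i`` so folds are independent yet reproducible.
    """
    unique = sorted(set(subjects))
    if len(unique) < val_count + 2:
        raise ConfigurationError(
            f"need more than {val_count + 1} subjects for val_count={val_count}, "
            f"got {len(unique)}"
        )
    folds = []
    for i, test_subject in enumerate(unique):
        remainder = [s for s in unique if s != test_subject]
        rng = np.random.default_rng(seed + i)
        val_idx = rng.choice(len(remainder), size=val_count, replace=False)
        val = frozenset(remainder[j] for j in val_idx)
        train = frozenset(remainder) - val
        fold = Fold(train_subjects=train, val_subjects=val, test_subject=test_subject)
        fold.check_disjoint(frozenset(unique))
        folds.append(fold)
    return FoldPlan(folds=tuple(folds), val_count=val_count, seed=seed)


def confusion(predictions: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Count TP/TN/FP/FN with ``pain`` as the positive class."""
    if len(predictions) != len(truth):
        raise ValidationError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths"
        )
    tp = tn = fp = fn = 0
    for pred, true in zip(predictions, truth):
        if true == POSITIVE_CLASS:
            if pred == POSITIVE_CLASS:
                tp += 1
            else:
                fn += 1
        else:
            if pred == POSITIVE_CLASS:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(counts: ConfusionCounts) -> MetricValues:
    """Accuracy, precision and recall from confusion counts."""
    if counts.total == 0:
        raise ValidationError("metrics undefined for zero evaluated samples")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = (
        counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    )
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    if precision is None:
        logger.warning("precision undefined (no predicted positives)")
    if recall is None:
        logger.warning("recall undefined (no positive truths)")
    return MetricValues(accuracy=accuracy, precision=precision, recall=recall)


def _aggregate(values: list[Optional[float]]) -> dict:
    defined = [v for v in values if v is not None]
    n_undefined = len(values) - len(defined)
    if not defined:
        return {"mean": None, "std": None, "n_folds": 0, "n_undefined": n_undefined}
    arr = np.asarray(defined, dtype=float)
    return {
        "mean": float(arr.mean()),
        "std": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "n_folds": len(arr),
        "n_undefined": n_undefined,
    }


@dataclasses.dataclass
class EvalReport:
    per_fold: list[dict]
    aggregate: dict
    pooled: dict
    config: dict

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def table_row(self) -> dict:
        """One row of the align/augment comparison table (mean +- std)."""
        def fmt(metric: str) -> str:
            agg = self.aggregate[metric]
            if agg["mean"] is None:
                return "undefined"
            return f"{agg['mean']:.4f} (+- {agg['std']:.4f})"

        return {
            "approach": "LDM",
            "align": "Yes" if self.config.get("align", True) else "No",
            "augment": "Yes" if self.config.get("augment", True) else "No",
            "accuracy": fmt("accuracy"),
            "precision": fmt("precision"),
            "recall": fmt("recall"),
        }


def run_loso(
    manifest: Manifest,
    align: bool = True,
    augment_training: bool = True,
    alignment_config: AlignmentConfig = AlignmentConfig(),
    noise_config: NoiseConfig = NoiseConfig(),
    train_config: TrainConfig = TrainConfig(),
    val_count: int = 6,
    seed: int = 0,
) -> EvalReport:
    """Run the full leave-one-subject-out experiment on a labeled manifest.

    Per fold: align landmarks (unless disabled), vectorize, split by
    subject, train with per-epoch augmentation on training rows only,
    predict the held-out subject's images and compute metrics.  Fully
    reproducible from ``seed`` (per-fold model seeds are ``seed + i``).
    """
    if any(s.label is None for s in manifest.samples):
        raise ValidationError("manifest must have labels assigned before evaluation")

    processed = align_manifest(manifest, alignment_config) if align else manifest
    features = build_feature_matrix(
        processed, on_unaligned="warn" if align else "ignore"
    )
    subjects = sorted({s.subject_id for s in manifest.samples})
    plan = make_loso_folds(subjects, val_count=val_count, seed=seed)

    per_fold = []
    acc, prec, rec = [], [], []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for i, fold in enumerate(plan.folds):
        fold.check_disjoint(frozenset(subjects))
        train_rows = features[features["subject_id"].isin(fold.train_subjects)]
        val_rows = features[features["subject_id"].isin(fold.val_subjects)]
        test_rows = features[features["subject_id"] == fold.test_subject]
        try:
            model = fit(
                train_rows,
                val_rows,
                config=dataclasses.replace(train_config, seed=seed + i),
                noise=noise_config if augment_training else None,
            )
            preds = predict(model, test_rows)
        except Exception as exc:
            raise type(exc)(f"fold {i} (test subject {fold.test_subject}): {exc}") from exc
        counts = confusion(list(preds["label"]), list(test_rows["label"]))
        fold_metrics = metrics(counts)
        pooled_counts = pooled_counts + counts
        acc.append(fold_metrics.accuracy)
        prec.append(fold_metrics.precision)
        rec.append(fold_metrics.recall)
        per_fold.append(
            {
                "fold": i,
                "test_subject": fold.test_subject,
                "counts": dataclasses.asdict(counts),
                "metrics": dataclasses.asdict(fold_metrics),
                "selected_epoch": model.selected_epoch,
                "val_loss": model.selected_val_loss,
            }
        )

    pooled_metrics = metrics(pooled_counts)
    return EvalReport(
        per_fold=per_fold,
        aggregate={
            "accuracy": _aggregate(acc),
            "precision": _aggregate(prec),
            "recall": _aggregate(rec),
            "std_convention": "sample (ddof=1) across folds",
        },
        pooled={
            "counts": dataclasses.asdict(pooled_counts),
            "metrics": dataclasses.asdict(pooled_metrics),
        },
        config={
            "align": align,
            "augment": augment_training,
            "val_count": val_count,
            "seed": seed,
            "alignment": dataclasses.asdict(alignment_config),
            "noise": dataclasses.asdict(noise_config) if augment_training else None,
            "train": dataclasses.asdict(train_config),
        },
    )
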