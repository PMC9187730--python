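"""The three-hidden-layer MLP pain classifier.

Architecture: 96 input units (one per landmark coordinate offset), hidden
layers of 100, 100 and 500 rectified-linear units, and a 2-unit softmax
output over {no_pain, pain}.  Training runs a fixed 10-epoch budget of
Adam mini-batch steps (lr 0.01, batch 32) minimizing cross-entropy; on
each epoch the training rows are (optionally) re-augmented with fresh
noise, standard-scaled with statistics fit on those rows only, and the
validation loss is recorded.  The returned model is the checkpoint with
minimal validation loss (earliest epoch on ties).

Validation rows are always scaled with training-set statistics and never
contribute to the scaler or the gradients.  The network itself is
scikit-learn's MLPClassifier, driven one epoch at a time so that the
per-epoch scaling/augmentation and checkpoint selection are explicit.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from catpain.augmentation import NoiseConfig, augment
from catpain.errors import ConfigurationError, SchemaError, ValidationError
from catpain.features import FEATURE_COLUMNS, N_FEATURES

#: class order used for integer encoding; index 1 is the positive class
CLASS_ORDER = ("no_pain", "pain")


@dataclasses.dataclass(frozen=True)
class MLPSpec:
    hidden_layer_sizes: tuple[int, ...] = (100, 100, 500)
    n_inputs: int = N_FEATURES
    n_outputs: int = 2

    def __post_init__(self) -> None:
        if self.n_inputs != N_FEATURES or self.n_outputs != 2:
            raise ValidationError(
                f"classifier is defined on {N_FEATURES} features and 2 classes"
            )


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 0.01
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValidationError("epochs/batch_size >= 1 and learning_rate > 0 required")


@dataclasses.dataclass(frozen=True)
class ScalerStats:
    """Per-feature mean and sd; near-zero sds are replaced by 1."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "ScalerStats":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


@dataclasses.dataclass
class TrainedModel:
    network: MLPClassifier
    spec: MLPSpec
    scaler: ScalerStats
    history: list[dict]
    selected_epoch: int
    train_config: TrainConfig

    @property
    def selected_val_loss(self) -> float:
        return self.history[self.selected_epoch]["val_loss"]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "spec": dataclasses.asdict(self.spec),
            "train_config": dataclasses.asdict(self.train_config),
            "history": self.history,
            "selected_epoch": self.selected_epoch,
            "scaler": {"mean": self.scaler.mean.tolist(), "sd": self.scaler.sd.tolist()},
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        weights = {f"coef_{i}": w for i, w in enumerate(self.network.coefs_)}
        weights.update(
            {f"intercept_{i}": b for i, b in enumerate(self.network.intercepts_)}
        )
        np.savez(directory / "weights.npz", **weights)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        if meta.get("format_version") != 1:
            raise ValidationError("unsupported model format version")
        spec = MLPSpec(
            hidden_layer_sizes=tuple(meta["spec"]["hidden_layer_sizes"]),
            n_inputs=meta["spec"]["n_inputs"],
            n_outputs=meta["spec"]["n_outputs"],
        )
        train_config = TrainConfig(**meta["train_config"])
        scaler = ScalerStats(
            mean=np.asarray(meta["scaler"]["mean"], dtype=float),
            sd=np.asarray(meta["scaler"]["sd"], dtype=float),
        )
        network = _make_network(spec, train_config)
        with np.load(directory / "weights.npz") as npz:
            n_layers = len(spec.hidden_layer_sizes) + 1
            network.coefs_ = [npz[f"coef_{i}"] for i in range(n_layers)]
            network.intercepts_ = [npz[f"intercept_{i}"] for i in range(n_layers)]
        network.classes_ = np.array([0, 1])
        network.n_layers_ = n_layers + 1
        # sklearn parameterizes the binary softmax head as one logistic unit
        network.n_outputs_ = network.coefs_[-1].shape[1]
        network.out_activation_ = "logistic" if network.n_outputs_ == 1 else "softmax"
        network.n_features_in_ = spec.n_inputs
        return cls(
            network=network,
            spec=spec,
            scaler=scaler,
            history=meta["history"],
            selected_epoch=meta["selected_epoch"],
            train_config=train_config,
        )


def _make_network(spec: MLPSpec, config: TrainConfig) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=spec.hidden_layer_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=config.batch_size,
        alpha=0.0,
        shuffle=True,
        random_state=config.seed,
        max_iter=1,
    )


def _split_xy(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    labels = features["label"].astype(str)
    bad = sorted(set(labels) - set(CLASS_ORDER))
    if bad:
        raise ValidationError(f"unknown labels in feature table: {bad}")
    y = (labels == CLASS_ORDER[1]).to_numpy().astype(int)
    return X, y


def fit(
    train: pd.DataFrame,
    val: pd.DataFrame,
    config: TrainConfig = TrainConfig(),
    noise: Optional[NoiseConfig] = None,
) -> TrainedModel:
    """Train the MLP with per-epoch scaling/augmentation and checkpointing.

    ``noise=None`` disables augmentation; otherwise each epoch prepends
    fresh noisy copies of the training rows (or a single fixed draw when
    the noise config says not to resample).
    """
    X_train_raw, y_train = _split_xy(train)
    X_val_raw, y_val = _split_xy(val)
    if len(X_val_raw) == 0:
        raise ConfigurationError("empty validation set: checkpoint selection undefined")
    if len(np.unique(y_train)) < 2:
        raise ConfigurationError("training set must contain both classes")

    spec = MLPSpec()
    network = _make_network(spec, config)
    aug_rng = np.random.default_rng(config.seed)

    fixed_epoch_table: Optional[pd.DataFrame] = None
    if noise is not None and not noise.resample_each_epoch:
        fixed_epoch_table = augment(train, noise, aug_rng)

    history: list[dict] = []
    best: Optional[dict] = None
    for epoch in range(config.epochs):
        if noise is None:
            epoch_table = train
        elif fixed_epoch_table is not None:
            epoch_table = fixed_epoch_table
        else:
            epoch_table = augment(train, noise, aug_rng)
        X_epoch, y_epoch = _split_xy(epoch_table)
        scaler = ScalerStats.fit(X_epoch)
        X_scaled = scaler.transform(X_epoch)
        network.partial_fit(X_scaled, y_epoch, classes=np.array([0, 1]))

        train_loss = float(
            log_loss(y_epoch, network.predict_proba(X_scaled), labels=[0, 1])
        )
        X_val = scaler.transform(X_val_raw)
        val_loss = float(
            log_loss(y_val, network.predict_proba(X_val), labels=[0, 1])
        )
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if best is None or val_loss < best["val_loss"]:
            best = {
                "val_loss": val_loss,
                "epoch": epoch,
                "coefs": copy.deepcopy(network.coefs_),
                "intercepts": copy.deepcopy(network.intercepts_),
                "scaler": scaler,
            }

    assert best is not None
    network.coefs_ = best["coefs"]
    network.intercepts_ = best["intercepts"]
    return TrainedModel(
        network=network,
        spec=spec,
        scaler=best["scaler"],
        history=history,
        selected_epoch=best["epoch"],
        train_config=config,
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Class probabilities and hard labels for each row.

    Ties at probability exactly 0.5 resolve to ``pain`` — the welfare-
    motivated choice of favoring sensitivity.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    if len(features) == 0:
        return pd.DataFrame(columns=["sample_id", "p_no_pain", "p_pain", "label"])
    X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    proba = model.network.predict_proba(model.scaler.transform(X))
    labels = np.where(proba[:, 1] >= 0.5, CLASS_ORDER[1], CLASS_ORDER[0])
    out = pd.DataFrame(
        {
            "sample_id": features["sample_id"].to_numpy()
            if "sample_id" in features.columns
            else np.arange(len(features)),
            "p_no_pain": proba[:, 0],
            "p_pain": proba[:, 1],
            "label": labels,
        }
    )
    return out
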