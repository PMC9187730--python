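import numpy as np
import pandas as pd
import pytest

from catpain.data_model import LandmarkSet, Manifest, Sample, Timepoint, assign_labels
from catpain.features import FEATURE_COLUMNS
from catpain.synthetic_data import SynthConfig, generate, make_template


@pytest.fixture(scope="session")
def template() -> LandmarkSet:
    return make_template()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_manifest() -> Manifest:
    """8 subjects x 3 images per class, moderate separation, posed."""
    return generate(
        SynthConfig(n_subjects=8, images_per_subject_per_class=3, effect_size=5.0, seed=7)
    )


def make_samples(rows) -> Manifest:
    """Build a manifest from (sample_id, subject_id, timepoint) tuples."""
    base = make_template()
    samples = [
        Sample(
            sample_id=sid,
            subject_id=subj,
            timepoint=Timepoint(tp),
            landmarks=base,
        )
        for sid, subj, tp in rows
    ]
    return Manifest(samples)


def blob_feature_table(
    n_per_class: int,
    separation: float,
    seed: int,
    n_subjects: int = 4,
) -> pd.DataFrame:
    """Two Gaussian blobs in 96-D as a labeled feature table.

    Class means differ by ``separation`` along every coordinate; unit
    within-class sd.  Subjects are assigned round-robin (only used for
    bookkeeping columns).
    """
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, 96))
    X1 = rng.normal(separation, 1.0, size=(n_per_class, 96))
    X = np.vstack([X0, X1])
    labels = ["no_pain"] * n_per_class + ["pain"] * n_per_class
    n = 2 * n_per_class
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    df.insert(0, "label", labels)
    df.insert(0, "subject_id", [f"s{i % n_subjects}" for i in range(n)])
    df.insert(0, "sample_id", [f"blob{i:04d}" for i in range(n)])
    return df


@pytest.fixture()
def separable_features() -> tuple[pd.DataFrame, pd.DataFrame]:
    train = blob_feature_table(100, separation=2.0, seed=5)
    val = blob_feature_table(30, separation=2.0, seed=6)
    return train, val
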