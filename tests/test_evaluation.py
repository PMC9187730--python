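"""LOSO fold construction, confusion counting, metrics, full runs."""

import itertools

import numpy as np
import pytest

from catpain.errors import ConfigurationError, ValidationError
from catpain.evaluation import (
    ConfusionCounts,
    confusion,
    make_loso_folds,
    metrics,
    run_loso,
)
from catpain.model import TrainConfig
from catpain.synthetic_data import SynthConfig, generate


class TestMakeLosoFolds:
    def test_canonical_26_subjects_split_19_6_1(self):
        subjects = [f"cat{i:02d}" for i in range(26)]
        plan = make_loso_folds(subjects, val_count=6, seed=0)
        assert len(plan.folds) == 26
        for fold in plan.folds:
            assert len(fold.train_subjects) == 19
            assert len(fold.val_subjects) == 6

    def test_each_subject_tests_exactly_once(self):
        subjects = [f"s{i}" for i in range(8)]
        plan = make_loso_folds(subjects, val_count=2, seed=1)
        assert sorted(f.test_subject for f in plan.folds) == sorted(subjects)
        for fold in plan.folds:
            assert len(fold.train_subjects) == 5
            assert len(fold.val_subjects) == 2
            assert not fold.train_subjects & fold.val_subjects
            assert fold.test_subject not in fold.train_subjects | fold.val_subjects

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            make_loso_folds(["a", "b", "c"], val_count=6, seed=0)

    def test_seed_controls_validation_draw(self):
        subjects = [f"s{i}" for i in range(10)]
        plan_a = make_loso_folds(subjects, val_count=3, seed=0)
        plan_b = make_loso_folds(subjects, val_count=3, seed=0)
        plan_c = make_loso_folds(subjects, val_count=3, seed=99)
        assert plan_a == plan_b
        assert any(
            fa.val_subjects != fc.val_subjects
            for fa, fc in zip(plan_a.folds, plan_c.folds)
        )


class TestConfusion:
    def test_hand_enumerated_example(self):
        truth = ["pain", "pain", "pain", "no_pain", "no_pain"]
        pred = ["pain", "pain", "no_pain", "pain", "no_pain"]
        counts = confusion(pred, truth)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (2, 1, 1, 1)

    def test_perfect_predictions(self):
        truth = ["pain", "no_pain", "pain"]
        counts = confusion(truth, truth)
        assert counts.fp == counts.fn == 0
        assert counts.total == 3

    def test_all_predicted_pain(self):
        truth = ["pain", "no_pain", "no_pain"]
        counts = confusion(["pain"] * 3, truth)
        assert counts.tn == 0 and counts.fn == 0
        assert counts.tp == 1 and counts.fp == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion(["pain"], ["pain", "no_pain"])


class TestMetrics:
    def test_printed_formula_example(self):
        m = metrics(ConfusionCounts(tp=3, tn=2, fp=1, fn=2))
        assert m.accuracy == 0.625
        assert m.precision == 0.75
        assert m.recall == 0.6

    def test_all_true_positives(self):
        m = metrics(ConfusionCounts(tp=5, tn=0, fp=0, fn=0))
        assert m.accuracy == m.precision == m.recall == 1.0

    def test_undefined_precision_zero_recall(self):
        m = metrics(ConfusionCounts(tp=0, tn=2, fp=0, fn=3))
        assert m.precision is None
        assert m.recall == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_brute_force_for_all_small_tables(self):
        """Exhaustive oracle: for every confusion table with at most 12
        samples, rebuild the label sequences and count correctness directly."""
        for tp, tn, fp, fn in itertools.product(range(13), repeat=4):
            total = tp + tn + fp + fn
            if total == 0 or total > 12:
                continue
            truth = ["pain"] * (tp + fn) + ["no_pain"] * (tn + fp)
            pred = (
                ["pain"] * tp + ["no_pain"] * fn + ["no_pain"] * tn + ["pain"] * fp
            )
            counts = confusion(pred, truth)
            assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)
            m = metrics(counts)
            n_correct = sum(p == t for p, t in zip(pred, truth))
            assert m.accuracy == n_correct / total
            if tp + fp > 0:
                n_pred_pain = sum(p == "pain" for p in pred)
                n_correct_pain = sum(
                    p == t == "pain" for p, t in zip(pred, truth)
                )
                assert m.precision == n_correct_pain / n_pred_pain
            if tp + fn > 0:
                n_true_pain = sum(t == "pain" for t in truth)
                assert m.recall == sum(
                    p == t == "pain" for p, t in zip(pred, truth)
                ) / n_true_pain


@pytest.fixture(scope="module")
def tiny_run():
    manifest = generate(
        SynthConfig(n_subjects=8, images_per_subject_per_class=3, effect_size=6.0, seed=21)
    )
    report = run_loso(
        manifest,
        align=True,
        augment_training=True,
        train_config=TrainConfig(seed=21),
        val_count=2,
        seed=21,
    )
    return manifest, report


class TestRunLoso:
    def test_one_fold_per_subject_all_test_images_scored(self, tiny_run):
        manifest, report = tiny_run
        assert len(report.per_fold) == 8
        for fold in report.per_fold:
            n = sum(
                1 for s in manifest.samples if s.subject_id == fold["test_subject"]
            )
            assert sum(fold["counts"].values()) == n

    def test_aggregate_mean_is_arithmetic_mean_of_folds(self, tiny_run):
        _, report = tiny_run
        fold_acc = [f["metrics"]["accuracy"] for f in report.per_fold]
        assert np.isclose(report.aggregate["accuracy"]["mean"], np.mean(fold_acc))
        assert np.isclose(
            report.aggregate["accuracy"]["std"], np.std(fold_acc, ddof=1)
        )

    def test_pooled_counts_sum_over_folds(self, tiny_run):
        _, report = tiny_run
        for key in ("tp", "tn", "fp", "fn"):
            assert report.pooled["counts"][key] == sum(
                f["counts"][key] for f in report.per_fold
            )

    def test_reruns_are_identical(self, tiny_run):
        manifest, report = tiny_run
        again = run_loso(
            manifest,
            align=True,
            augment_training=True,
            train_config=TrainConfig(seed=21),
            val_count=2,
            seed=21,
        )
        assert again.per_fold == report.per_fold
        assert again.aggregate == report.aggregate

    def test_unlabeled_manifest_rejected(self):
        from conftest import make_samples

        manifest = make_samples(
            [("a", "s1", "pre_surgery"), ("b", "s2", "post_surgery_1h")]
        )
        with pytest.raises(ValidationError):
            run_loso(manifest)

    def test_table_row_format(self, tiny_run):
        _, report = tiny_run
        row = report.table_row()
        assert row["approach"] == "LDM"
        assert row["align"] == "Yes" and row["augment"] == "Yes"
        assert "(+-" in row["accuracy"]
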