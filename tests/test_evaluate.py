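"""Split protocols, the two-branch classifier contract, and metrics."""

import numpy as np
import pandas as pd
import pytest

from pmsfe import (
    ClassifierSpec,
    TwoBranchClassifier,
    compare_channel_modes,
    evaluate,
    make_cv_folds,
    make_loso_splits,
    make_split,
    train_classifier,
)


def toy_manifest(n_subjects=3, per_cell=10):
    rows = []
    tid = 1
    for s in range(1, n_subjects + 1):
        for lv in (1, 2, 3, 4):
            for _ in range(per_cell):
                rows.append((tid, s, lv))
                tid += 1
    return pd.DataFrame(rows, columns=["trial_id", "subject_id", "load_level"])


class TestMakeSplit:
    def test_ten_per_cell_splits_exactly_622(self):
        manifest = toy_manifest(per_cell=10)
        plan = make_split(manifest, seed=0)
        for part, want in zip((plan.train_ids, plan.val_ids, plan.test_ids), (6, 2, 2)):
            sub = manifest[manifest["trial_id"].isin(part)]
            counts = sub.groupby(["subject_id", "load_level"]).size()
            assert (counts == want).all()

    def test_partition_property(self):
        manifest = toy_manifest(per_cell=7)
        plan = make_split(manifest, seed=3)
        ids = np.sort(plan.all_ids())
        np.testing.assert_array_equal(ids, np.sort(manifest["trial_id"].to_numpy()))
        assert not (set(plan.train_ids) & set(plan.val_ids))
        assert not (set(plan.train_ids) & set(plan.test_ids))
        assert not (set(plan.val_ids) & set(plan.test_ids))

    def test_all_in_train_when_ratios_100(self):
        manifest = toy_manifest(per_cell=5)
        plan = make_split(manifest, ratios=(1.0, 0.0, 0.0), seed=0)
        assert len(plan.train_ids) == len(manifest)
        assert len(plan.val_ids) == 0 and len(plan.test_ids) == 0

    def test_seeds_change_assignment_but_not_counts(self):
        manifest = toy_manifest(per_cell=10)
        a = make_split(manifest, seed=1)
        b = make_split(manifest, seed=2)
        assert set(a.train_ids) != set(b.train_ids)
        assert len(a.train_ids) == len(b.train_ids)
        assert len(a.test_ids) == len(b.test_ids)
        # same seed reproduces the split exactly
        np.testing.assert_array_equal(a.train_ids, make_split(manifest, seed=1).train_ids)

    def test_tiny_cells_warn(self):
        manifest = toy_manifest(per_cell=2)
        with pytest.warns(UserWarning, match="best-effort"):
            make_split(manifest, seed=0)


class TestCVAndLoso:
    def test_eight_per_stratum_gives_two_per_fold(self):
        manifest = toy_manifest(per_cell=8)
        cv = make_cv_folds(manifest, k=4, seed=0)
        for fold in cv.folds:
            sub = manifest[manifest["trial_id"].isin(fold)]
            counts = sub.groupby(["subject_id", "load_level"]).size()
            assert (counts == 2).all()

    def test_every_trial_validates_exactly_once(self):
        manifest = toy_manifest(per_cell=8)
        cv = make_cv_folds(manifest, k=4, seed=1)
        seen = np.concatenate(cv.folds)
        np.testing.assert_array_equal(np.sort(seen), manifest["trial_id"].to_numpy())
        n_pairs = sum(1 for _ in cv.iter_splits())
        assert n_pairs == 4

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_cv_folds(toy_manifest(), k=1)

    def test_loso_one_split_per_subject_with_no_leakage(self):
        manifest = toy_manifest(n_subjects=13, per_cell=2)
        splits = make_loso_splits(manifest)
        assert len(splits) == 13
        all_test = []
        for s in splits:
            train_subjects = set(
                manifest[manifest["trial_id"].isin(s.train_ids)]["subject_id"]
            )
            assert s.test_subject not in train_subjects
            all_test.append(s.test_ids)
        np.testing.assert_array_equal(
            np.sort(np.concatenate(all_test)), manifest["trial_id"].to_numpy()
        )

    def test_loso_needs_two_subjects(self):
        with pytest.raises(ValueError):
            make_loso_splits(toy_manifest(n_subjects=1))


def linearly_separable_maps(n_per_class=24, channels=6, seed=0):
    """Class-dependent mean patterns + small noise: trivially separable."""
    rng = np.random.default_rng(seed)
    maps, labels = [], []
    for lv in (1, 2, 3, 4):
        mean = np.zeros((channels, 4, 4))
        mean[:, (lv - 1) % 4, :] = 3.0
        maps.append(mean + 0.05 * rng.standard_normal((n_per_class, channels, 4, 4)))
        labels.extend([lv] * n_per_class)
    return np.concatenate(maps), np.array(labels)


class TestTwoBranchClassifier:
    def test_perfectly_separable_data_is_learned(self):
        maps, labels = linearly_separable_maps()
        spec = ClassifierSpec(epochs=60, lr=0.01, seed=0)
        model, history = train_classifier(maps, labels, spec)
        assert np.mean(model.predict(maps) == labels) == 1.0
        assert np.all(np.isfinite(history["train_loss"]))
        assert len(history["train_loss"]) == 60

    def test_branches_are_independent(self):
        maps, labels = linearly_separable_maps()
        spec = ClassifierSpec(epochs=5, seed=0)
        model, _ = train_classifier(maps, labels, spec)
        zeroed = maps.copy()
        zeroed[:, 3:] = 0.0  # wipe branch-2 input
        acts_a = model.branch_activations(maps, branch=0)
        acts_b = model.branch_activations(zeroed, branch=0)
        for a, b in zip(acts_a, acts_b):
            np.testing.assert_array_equal(a, b)

    def test_spectral3_mode_uses_single_branch(self):
        maps, labels = linearly_separable_maps()
        spec = ClassifierSpec(channel_mode="spectral3", epochs=5, seed=0)
        model, _ = train_classifier(maps, labels, spec)
        assert len(model._params["branches"]) == 1

    def test_validation_loss_is_tracked_and_finite(self):
        maps, labels = linearly_separable_maps()
        manifest = pd.DataFrame(
            {
                "trial_id": np.arange(1, len(labels) + 1),
                "subject_id": 1,
                "load_level": labels,
            }
        )
        split = make_split(manifest, seed=0)
        spec = ClassifierSpec(epochs=8, seed=0)
        _, history = train_classifier(maps, labels, spec, split)
        assert len(history["val_loss"]) == 8
        assert np.all(np.isfinite(history["val_loss"]))
        assert history["best_epoch"] is not None

    def test_training_is_seed_deterministic(self):
        maps, labels = linearly_separable_maps()
        spec = ClassifierSpec(epochs=10, seed=4)
        m1, h1 = train_classifier(maps, labels, spec)
        m2, h2 = train_classifier(maps, labels, spec)
        assert h1["train_loss"] == h2["train_loss"]
        np.testing.assert_array_equal(m1._params["W_out"], m2._params["W_out"])

    def test_save_load_roundtrip(self, tmp_path):
        maps, labels = linearly_separable_maps()
        spec = ClassifierSpec(epochs=10, lr=0.01, seed=0)
        model, _ = train_classifier(maps, labels, spec)
        model.save(tmp_path / "model.npz")
        back = TwoBranchClassifier.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(model.predict(maps), back.predict(maps))


class _FixedPredictor:
    def __init__(self, pred):
        self._pred = np.asarray(pred)

    def predict(self, maps):
        return self._pred[: len(maps)]


class TestEvaluate:
    def test_perfect_predictor_gives_identity_confusion(self):
        labels = np.repeat([1, 2, 3, 4], 10)
        maps = np.zeros((40, 6, 2, 2))
        report = evaluate(_FixedPredictor(labels), maps, labels)
        assert report.accuracy == 1.0
        np.testing.assert_array_equal(np.diag(report.confusion), [10, 10, 10, 10])
        assert report.confusion.sum() == 40

    def test_uniform_random_predictor_near_chance(self):
        rng = np.random.default_rng(0)
        n = 4000
        labels = np.repeat([1, 2, 3, 4], n // 4)
        pred = rng.integers(1, 5, size=n)
        report = evaluate(_FixedPredictor(pred), np.zeros((n, 6, 2, 2)), labels)
        sd = np.sqrt(0.25 * 0.75 / n)
        assert abs(report.accuracy - 0.25) < 3 * sd

    def test_confusion_rows_sum_to_class_counts(self):
        labels = np.array([1, 1, 2, 3, 3, 3, 4])
        pred = np.array([1, 2, 2, 3, 1, 3, 4])
        report = evaluate(_FixedPredictor(pred), np.zeros((7, 6, 2, 2)), labels)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), [2, 1, 3, 1])
        norm = report.confusion_normalized()
        np.testing.assert_allclose(norm.sum(axis=1), 1.0)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_FixedPredictor([1]), np.zeros((0, 6, 2, 2)), np.array([]))


class TestCompareChannelModes:
    def test_identical_information_gives_near_zero_increase(self):
        # duplicate the raw channels into the enhanced slots: both modes see
        # the same information, so the increased rate should be ~0
        maps, labels = linearly_separable_maps(channels=3, seed=1)
        maps6 = np.concatenate([maps, maps], axis=1)
        manifest = pd.DataFrame(
            {
                "trial_id": np.arange(1, len(labels) + 1),
                "subject_id": np.tile([1, 2], len(labels) // 2),
                "load_level": labels,
            }
        )
        spec = ClassifierSpec(epochs=40, lr=0.01)
        table = compare_channel_modes(maps6, labels, manifest, spec, seeds=[0, 1])
        assert list(table["mode"]) == ["spectral3", "pmsfe6"]
        assert set(table.columns) == {
            "mode", "mean_accuracy_pct", "std_accuracy", "increased_rate_pp",
        }
        # separable either way: both at ceiling, difference vanishes
        assert abs(table["increased_rate_pp"].iloc[1]) < 5.0
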