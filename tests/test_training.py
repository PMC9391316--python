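"""Training loops: PK batching, classifier, embedder, evaluation."""

import numpy as np
import pytest

from particleprint import (TrainConfig, classify_out_of_sample,
                           confusion_matrix, make_pk_batches, predict,
                           render_class, train_classifier, train_embedder)
from particleprint.nn import ClassifierModel
from particleprint.synthetic import default_study_specs
from conftest import make_split_data


class TestMakePkBatches:
    def test_batch_size_is_classes_times_per_class(self):
        labels = np.repeat(np.arange(8), 64)
        batches = list(make_pk_batches(labels, per_class=32, seed=0))
        assert all(len(b) == 256 for b in batches)
        for b in batches:
            counts = np.bincount(labels[b], minlength=8)
            assert np.all(counts == 32)

    def test_same_seed_reproduces_batch_sequence(self):
        labels = np.repeat(np.arange(3), 70)
        b1 = [b.tolist() for b in make_pk_batches(labels, 16, seed=5)]
        b2 = [b.tolist() for b in make_pk_batches(labels, 16, seed=5)]
        assert b1 == b2
        b3 = [b.tolist() for b in make_pk_batches(labels, 16, seed=6)]
        assert b1 != b3

    def test_per_image_appearance_bound_over_one_epoch(self):
        labels = np.concatenate([np.zeros(33, int), np.ones(100, int),
                                 np.full(64, 2)])
        seen = np.zeros(len(labels), int)
        for b in make_pk_batches(labels, per_class=32, seed=1):
            seen[b] += 1
        for cls in range(3):
            n_k = (labels == cls).sum()
            bound = -(-n_k // 32)
            assert seen[labels == cls].max() <= bound

    def test_small_class_falls_back_to_replacement_with_warning(self):
        labels = np.concatenate([np.zeros(8, int), np.ones(40, int)])
        with pytest.warns(UserWarning, match="replacement"):
            batches = list(make_pk_batches(labels, per_class=16, seed=0))
        assert all(np.bincount(labels[b])[0] == 16 for b in batches)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            list(make_pk_batches(np.zeros(10, int), 4, seed=0))


class TestTrainClassifier:
    def test_separable_classes_reach_high_test_accuracy(self, four_class_data,
                                                        four_class_model):
        model, _ = four_class_model
        pred = predict(model, four_class_data["test"])
        truth = np.array([im.label for im in four_class_data["test"]])
        cm = confusion_matrix(pred, truth, model.labels)
        assert np.all(cm.diagonal() >= 0.9)

    def test_loss_decreases_over_training(self, four_class_model):
        _, log = four_class_model
        assert len(log) == 15
        assert log["train_loss"].iloc[-1] <= log["train_loss"].iloc[0]

    def test_step_count_matches_ceil_arithmetic(self):
        specs = default_study_specs()[:2]
        data = make_split_data(specs, 5, seed=1)   # 4 train images per class
        _, log = train_classifier(data, TrainConfig(epochs=1, seed=0))
        assert log["steps"].iloc[0] == 1           # ceil(8 / 256)

    def test_seeded_runs_are_identical(self):
        specs = default_study_specs()[:2]
        data = make_split_data(specs, 30, seed=1)
        cfg = TrainConfig(epochs=2, seed=11)
        _, log1 = train_classifier(data, cfg)
        _, log2 = train_classifier(data, cfg)
        assert log1["train_loss"].tolist() == log2["train_loss"].tolist()

    def test_subtle_pair_above_chance_below_separable(self, subtle_pair_data,
                                                      subtle_pair_model,
                                                      four_class_data,
                                                      four_class_model):
        model, _ = subtle_pair_model
        pred = predict(model, subtle_pair_data["test"])
        truth = np.array([im.label for im in subtle_pair_data["test"]])
        acc = float((pred == truth).mean())
        assert acc > 0.5
        sep_model, _ = four_class_model
        sep_pred = predict(sep_model, four_class_data["test"])
        sep_truth = np.array([im.label for im in four_class_data["test"]])
        sep_acc = float((sep_pred == sep_truth).mean())
        assert acc < sep_acc

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            train_classifier({"train": [], "test": []}, TrainConfig(seed=0))


class TestEvaluation:
    def test_perfect_predictions_give_identity_matrix(self):
        labels = ["a", "b", "c"]
        truth = np.array(labels * 4)
        cm = confusion_matrix(truth.copy(), truth, labels)
        np.testing.assert_allclose(cm.matrix, np.eye(3))

    def test_hand_counted_errors(self):
        labels = ["a", "b", "c"]
        truth = np.array(["a"] * 4 + ["b"] * 2 + ["c"] * 2)
        pred = np.array(["a", "a", "b", "c", "b", "a", "c", "c"])
        cm = confusion_matrix(pred, truth, labels)
        np.testing.assert_allclose(cm.matrix, [
            [0.5, 0.25, 0.25], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])

    def test_rows_sum_to_one(self, four_class_data, four_class_model):
        model, _ = four_class_model
        pred = predict(model, four_class_data["test"])
        truth = np.array([im.label for im in four_class_data["test"]])
        cm = confusion_matrix(pred, truth, model.labels)
        np.testing.assert_allclose(cm.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_unseen_truth_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.array(["a"]), np.array(["z"]), ["a", "b"])

    def test_out_of_sample_row_sums_to_one_and_finds_twin(self, four_class_model):
        model, _ = four_class_model
        # foreign class drawn from the same recipe as 'fa_pal'
        twin = default_study_specs()[3]
        import dataclasses
        foreign_spec = dataclasses.replace(twin, name="foreign")
        foreign = render_class(foreign_spec, 100, seed=9, class_idx=7)
        row = classify_out_of_sample(model, foreign)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)
        assert row.idxmax() == "fa_pal"

    def test_checkpoint_roundtrip(self, four_class_model, tmp_path,
                                  four_class_data):
        model, _ = four_class_model
        model.save(tmp_path / "clf")
        loaded = ClassifierModel.load(tmp_path / "clf")
        sample = four_class_data["test"][:16]
        assert predict(loaded, sample).tolist() == predict(model, sample).tolist()


class TestTrainEmbedder:
    def test_selected_snapshot_is_validation_minimum(self, three_class_embedder):
        model, log, _ = three_class_embedder
        assert log.attrs["best_val_loss"] == pytest.approx(log["val_loss"].min())
        assert log["val_loss"].iloc[log.attrs["best_epoch"] - 1] == pytest.approx(
            log.attrs["best_val_loss"])

    def test_validation_loss_improves_from_start(self, three_class_embedder):
        _, log, _ = three_class_embedder
        assert log.attrs["best_val_loss"] < log["val_loss"].iloc[0]

    def test_patience_zero_stops_at_first_stall(self):
        specs = default_study_specs()[:2]
        data = make_split_data(specs, 60, seed=1, splits=("train", "val"),
                               fractions=(0.8, 0.2))
        cfg = TrainConfig(seed=0, patience=0, per_class_batch=8, max_epochs=50)
        _, log = train_embedder(data, cfg)
        val = log["val_loss"].to_numpy()
        # the run ends exactly one epoch after the first non-improvement
        run_min = np.minimum.accumulate(val)
        stalls = np.flatnonzero(val[1:] >= run_min[:-1]) + 1
        assert len(log) == (stalls[0] + 1 if len(stalls) else 50)

    def test_missing_class_in_val_split_rejected(self):
        specs = default_study_specs()[:2]
        data = make_split_data(specs, 40, seed=1, splits=("train", "val"),
                               fractions=(0.8, 0.2))
        data["val"] = [im for im in data["val"] if im.label == specs[0].name]
        with pytest.raises(ValueError, match="absent"):
            train_embedder(data, TrainConfig(seed=0))
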