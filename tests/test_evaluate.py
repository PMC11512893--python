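import numpy as np
import pytest

from spinalzfnet import evaluate
from spinalzfnet.errors import ConfigurationError
from spinalzfnet.evaluate import (ConfusionCounts, TrainConfig,
                                  TrainingController, compute_metrics,
                                  kfold_evaluate, learning_set_evaluate,
                                  roc_curves)
from spinalzfnet.phantom import CLASSES, PhantomSpec, generate


class StubModel:
    """A checkpointable stand-in whose 'weights' are a single number."""

    def __init__(self):
        self.value = 0.0

    def state_dict(self):
        return {"value": self.value}

    def load_state_dict(self, state):
        self.value = state["value"]


class TestTrainConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError, match="lr"):
            TrainConfig(lr=0.0)
        with pytest.raises(ConfigurationError, match="patience"):
            TrainConfig(plateau_patience=0)
        with pytest.raises(ConfigurationError, match="batch"):
            TrainConfig(batch_size=0)


class TestTrainingController:
    def test_lr_halves_every_five_flat_epochs(self):
        """Validation accuracy improves at epoch 1 then never again: the LR
        is halved at epochs 6, 11, 16, … (patience-5 cadence)."""
        controller = TrainingController(TrainConfig(lr=0.1, max_epochs=100))
        controller.update(1, 0.5)
        for epoch in range(2, 22):
            controller.update(epoch, 0.5)  # never beats best + min_delta
        assert controller.lr_halving_epochs[:4] == [6, 11, 16, 21]
        assert controller.lr == pytest.approx(0.1 * 0.5 ** 4)

    def test_sub_min_delta_improvement_does_not_reset(self):
        controller = TrainingController(TrainConfig(lr=0.1))
        controller.update(1, 0.5)
        for epoch in range(2, 7):
            controller.update(epoch, 0.5 + 5e-5)  # below min_delta=1e-4
        assert controller.lr_halving_epochs == [6]

    def test_early_stop_bound(self):
        config = TrainConfig(early_stop_patience=50)
        controller = TrainingController(config)
        stopped_at = None
        for epoch in range(1, 200):
            improving = epoch <= 3
            if controller.update(epoch, 0.5 + 0.01 * epoch if improving else 0.0):
                stopped_at = epoch
                break
        assert stopped_at is not None
        assert stopped_at <= controller.best_epoch + 50 + 1

    def test_best_checkpoint_restored_not_last(self):
        """A scripted metric sequence whose last epoch is worse: the restored
        model must carry the best epoch's weights."""
        controller = TrainingController(TrainConfig())
        stub = StubModel()
        scripted = [0.6, 0.9, 0.7, 0.5]
        for epoch, metric in enumerate(scripted, start=1):
            stub.value = float(epoch)  # "weights" change each epoch
            controller.update(epoch, metric, stub)
        controller.restore_best(stub)
        assert stub.value == 2.0  # epoch of the 0.9 peak
        assert controller.best_epoch == 2


def metrics_brute_force(y_true, y_pred, positive):
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive and p == positive:
            tp += 1
        elif t != positive and p != positive:
            tn += 1
        elif t != positive and p == positive:
            fp += 1
        else:
            fn += 1
    acc = (tp + tn) / max(1, tp + tn + fp + fn)
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return acc, sens, spec, prec, f1


class TestMetrics:
    def test_binary_arithmetic_examples(self):
        counts = ConfusionCounts(np.array([[50, 5], [5, 40]]))
        report = compute_metrics(counts, class_names=("pos", "neg"))
        assert report.per_class["pos"]["accuracy"] == pytest.approx(90.0)
        assert report.per_class["pos"]["sensitivity"] == pytest.approx(
            100 * 50 / 55)

    def test_f1_equals_precision_when_equal_to_sensitivity(self):
        counts = ConfusionCounts(np.array([[40, 10], [10, 40]]))
        report = compute_metrics(counts, class_names=("a", "b"))
        a = report.per_class["a"]
        assert a["precision"] == pytest.approx(a["sensitivity"])
        assert a["f1"] == pytest.approx(a["precision"])

    def test_matches_brute_force_on_random_predictions(self, rng):
        """100 random 4-class truth/prediction vectors: per-class one-vs-rest
        metrics match per-sample counting exactly."""
        for _ in range(100):
            y_true = rng.integers(0, 4, size=30)
            y_pred = rng.integers(0, 4, size=30)
            counts = ConfusionCounts.from_predictions(y_true, y_pred)
            report = compute_metrics(counts)
            for idx, name in enumerate(CLASSES):
                expected = metrics_brute_force(y_true, y_pred, idx)
                got = report.per_class[name]
                for key, value in zip(
                        ("accuracy", "sensitivity", "specificity",
                         "precision", "f1"),
                        expected):
                    assert got[key] == pytest.approx(100 * value, abs=1e-9)

    def test_confusion_identities(self, rng):
        y_true = rng.integers(0, 4, size=50)
        y_pred = rng.integers(0, 4, size=50)
        counts = ConfusionCounts.from_predictions(y_true, y_pred)
        assert counts.matrix.sum() == 50
        for idx in range(4):
            tp, tn, fp, fn = counts.one_vs_rest(idx)
            assert tp + fn == (y_true == idx).sum()
            assert tp + fp == (y_pred == idx).sum()

    def test_zero_denominator_flagged_not_raised(self):
        counts = ConfusionCounts(np.zeros((4, 4), dtype=int))
        counts.matrix[1, 1] = 10  # only one class present
        report = compute_metrics(counts)
        assert any("zero denominator" in flag for flag in report.flags)
        assert report.per_class["normal"]["sensitivity"] == 0.0


class TestRoc:
    def test_perfectly_separable_scores_give_auc_one(self):
        y = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        proba = np.where(np.eye(4)[y] > 0, 0.97, 0.01)
        curves = roc_curves(y, proba)
        for name in CLASSES:
            assert curves[f"{name}_auc"] == pytest.approx(1.0)
        assert curves["micro_auc"] == pytest.approx(1.0)

    def test_uninformative_scores_give_auc_near_half(self, rng):
        y = rng.integers(0, 4, size=2000)
        proba = rng.random((2000, 4))
        proba /= proba.sum(axis=1, keepdims=True)
        curves = roc_curves(y, proba)
        assert curves["macro_auc"] == pytest.approx(0.5, abs=0.05)

    def test_micro_equals_per_class_for_mirror_symmetric_two_class(self, rng):
        """When every sample has a mirrored counterpart (same score for the
        opposite class), pooling duplicates the per-class problem and the
        micro curve coincides with each per-class curve."""
        s = rng.random(50)
        y = np.array([1] * 50 + [0] * 50)
        col1 = np.concatenate([s, 1 - s])
        proba = np.stack([1 - col1, col1], axis=1)
        curves = roc_curves(y, proba, class_names=("a", "b"))
        assert curves["micro_auc"] == pytest.approx(curves["a_auc"], abs=1e-9)
        assert curves["a_auc"] == pytest.approx(curves["b_auc"], abs=1e-9)

    def test_absent_class_reported_missing(self):
        y = np.array([0, 0, 1, 1])
        proba = np.full((4, 4), 0.25)
        curves = roc_curves(y, proba)
        assert curves["tumor_auc"] is None

    def test_unnormalised_rows_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            roc_curves(np.array([0, 1]), np.array([[0.9, 0.3], [0.1, 0.7]]))


def perfect_stub_trainer(train_samples, test_samples):
    y_true = np.array([CLASSES.index(s.label) for s in test_samples])
    proba = np.where(np.eye(4)[y_true] > 0, 0.97, 0.01)
    return y_true, y_true.copy(), proba


@pytest.fixture(scope="module")
def dataset():
    return generate(PhantomSpec(image_size=64, n_per_class=5, seed=9))


class TestProtocols:

    def test_kfold_perfect_stub_scores_100(self, dataset):
        reports, aggregate = kfold_evaluate(dataset, 4, perfect_stub_trainer,
                                            seed=0)
        assert len(reports) == 4
        assert aggregate.accuracy == pytest.approx(100.0)
        assert aggregate.f1 == pytest.approx(100.0)

    def test_kfold_test_folds_partition_dataset(self, dataset):
        seen = []

        def recording_trainer(train_samples, test_samples):
            seen.extend(id(s) for s in test_samples)
            return perfect_stub_trainer(train_samples, test_samples)

        kfold_evaluate(dataset, 5, recording_trainer, seed=1)
        assert sorted(seen) == sorted(id(s) for s in dataset)

    def test_kfold_validates_k(self, dataset):
        with pytest.raises(ValueError, match="K"):
            kfold_evaluate(dataset, 1, perfect_stub_trainer)

    def test_learning_set_split_sizes_and_provenance(self, dataset):
        sizes = {}

        def recording_trainer(train_samples, test_samples):
            sizes["train"] = len(train_samples)
            return perfect_stub_trainer(train_samples, test_samples)

        report = learning_set_evaluate(dataset, 50, recording_trainer, seed=0)
        assert sizes["train"] == len(dataset) // 2
        assert report.provenance["train_pct"] == 50

    def test_learning_set_metrics_match_direct_computation(self, dataset):
        """Frozen stub predictions produce the same report through the
        protocol as through compute_metrics directly (bypass oracle)."""
        frozen = {}

        def freezing_trainer(train_samples, test_samples):
            out = perfect_stub_trainer(train_samples, test_samples)
            frozen["y"] = out[0]
            return out

        report = learning_set_evaluate(dataset, 80, freezing_trainer, seed=0)
        direct = compute_metrics(
            ConfusionCounts.from_predictions(frozen["y"], frozen["y"]))
        assert report.accuracy == direct.accuracy
        assert report.f1 == direct.f1

    def test_kfold_aggregate_matches_pooled_on_equal_folds(self, dataset):
        """With equal-size folds and a deterministic stub, the mean of fold
        accuracies equals the pooled-prediction accuracy."""
        pooled = {"true": [], "pred": []}

        def stub(train_samples, test_samples):
            y_true, y_pred, proba = perfect_stub_trainer(train_samples,
                                                         test_samples)
            y_pred = y_pred.copy()
            y_pred[0] = (y_pred[0] + 1) % 4  # one error per fold
            pooled["true"].extend(y_true)
            pooled["pred"].extend(y_pred)
            return y_true, y_pred, None

        _, aggregate = kfold_evaluate(dataset, 4, stub, seed=0)
        pooled_acc = evaluate.overall_accuracy(
            ConfusionCounts.from_predictions(pooled["true"], pooled["pred"]))
        fold_size = len(dataset) // 4
        expected = 100.0 * (fold_size - 1) / fold_size
        assert pooled_acc == pytest.approx(expected)
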