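import numpy as np
import pytest

from dermrestore import (
    LesionHeadClassifier,
    TinyConvFeatures,
    TrainConfig,
    accuracy,
    attach_head,
    categorical_cross_entropy,
    generate_phantom_corpus,
    relu,
    run_experiment,
    softmax,
    split_dataset,
    train,
)


class TestPrimitives:
    def test_relu_definition_and_idempotence(self):
        x = np.array([-1.0, 0.0, 2.0])
        np.testing.assert_array_equal(relu(x), [0.0, 0.0, 2.0])
        np.testing.assert_array_equal(relu(np.array([-5.0, -0.1])), [0.0, 0.0])
        y = np.array([-3.0, 4.0])
        np.testing.assert_array_equal(relu(relu(y)), relu(y))

    def test_softmax_uniform_and_shift_invariance(self, rng):
        np.testing.assert_allclose(softmax(np.zeros(7)), np.full(7, 1 / 7))
        z = rng.normal(size=12)
        np.testing.assert_allclose(softmax(z), softmax(z + 3.7), atol=1e-12)
        assert softmax(z).sum() == pytest.approx(1.0, abs=1e-9)

    def test_softmax_log_ratio_example(self):
        out = softmax(np.log([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [1 / 6, 2 / 6, 3 / 6], atol=1e-12)

    def test_softmax_order_preserving(self, rng):
        z = rng.normal(size=9)
        assert (np.argsort(softmax(z)) == np.argsort(z)).all()

    def test_cross_entropy_closed_forms(self):
        perfect = np.eye(7)[[2]]
        assert categorical_cross_entropy(perfect, [2]) == pytest.approx(0.0, abs=1e-9)
        uniform = np.full((4, 7), 1 / 7)
        assert categorical_cross_entropy(uniform, [0, 1, 2, 3]) == pytest.approx(
            np.log(7), abs=1e-12
        )
        half = np.array([[0.5, 0.5, 0, 0, 0, 0, 0.0]])
        assert categorical_cross_entropy(half, [0]) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_cross_entropy_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            categorical_cross_entropy(np.array([[0.9, 0.4]]), [0])

    def test_accuracy_counting(self):
        pred = np.eye(4)[[0, 1, 2, 0]]
        assert accuracy(pred, [0, 1, 2, 3]) == 0.75
        assert accuracy(pred, [0, 1, 2, 0]) == 1.0
        assert accuracy(pred, [1, 2, 3, 1]) == 0.0


class TestSplit:
    def test_80_20_counts(self):
        labels = np.repeat(np.arange(7), 10)
        train_ids, val_ids = split_dataset(labels, 0.8, seed=0)
        assert len(train_ids) == 56 and len(val_ids) == 14

    def test_partition_and_stratification(self):
        labels = np.repeat(np.arange(7), 10)
        train_ids, val_ids = split_dataset(labels, 0.8, seed=3)
        union = np.sort(np.concatenate([train_ids, val_ids]))
        np.testing.assert_array_equal(union, np.arange(70))
        for c in range(7):
            assert (labels[val_ids] == c).sum() == 2

    def test_seed_determinism(self):
        labels = np.repeat(np.arange(7), 9)
        a = split_dataset(labels, 0.8, seed=5)
        b = split_dataset(labels, 0.8, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(np.array([]), 0.8, 0)


def _identity_backbone(x):
    return np.asarray(x, dtype=np.float64)


class TestHeadClassifier:
    def test_head_parameter_count_for_64_features(self, rng):
        feats = rng.normal(size=(70, 64))
        labels = np.repeat(np.arange(7), 10)
        clf = attach_head(_identity_backbone)
        clf.set_params(epochs=1)
        clf.fit(feats, labels)
        assert clf.coef_.size + clf.intercept_.size == 64 * 7 + 7  # = 455

    def test_probabilities_valid(self, rng):
        feats = rng.normal(size=(21, 8))
        labels = np.repeat(np.arange(7), 3)
        clf = LesionHeadClassifier(backbone=_identity_backbone, epochs=2)
        clf.fit(feats, labels)
        probs = clf.predict_proba(rng.normal(size=(5, 8)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_linearly_separable_toy_is_learned(self, rng):
        angles = 2 * np.pi * np.arange(7) / 7
        centers = 6.0 * np.stack([np.cos(angles), np.sin(angles)], axis=1)
        feats = np.concatenate(
            [c + rng.normal(scale=0.3, size=(100, 2)) for c in centers]
        )
        labels = np.repeat(np.arange(7), 100)
        clf = LesionHeadClassifier(backbone=_identity_backbone, epochs=25,
                                   random_state=0)
        clf.fit(feats, labels)
        assert clf.history_[-1].train_acc >= 0.95

    def test_training_trace_is_seed_deterministic(self, rng):
        feats = rng.normal(size=(35, 6))
        labels = np.tile(np.arange(7), 5)
        runs = []
        for _ in range(2):
            clf = LesionHeadClassifier(backbone=_identity_backbone, epochs=5,
                                       random_state=42)
            clf.fit(feats, labels)
            runs.append([(m.train_acc, m.train_loss) for m in clf.history_])
        assert runs[0] == runs[1]

    def test_backbone_is_frozen_during_training(self, rng):
        backbone = TinyConvFeatures(channels=(4, 8, 8))
        imgs = rng.integers(0, 256, size=(14, 32, 32, 3), dtype=np.uint8)
        before = backbone(imgs)
        clf = LesionHeadClassifier(backbone=backbone, epochs=2)
        clf.fit(imgs, np.tile(np.arange(7), 2))
        np.testing.assert_array_equal(backbone(imgs), before)

    def test_label_shuffle_control_stays_at_chance(self):
        images, labels = generate_phantom_corpus(10, image_size=(32, 32), seed=1)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(labels)
        cfg = TrainConfig(seed=0)
        _, history = train(
            images, shuffled, cfg, backbone=TinyConvFeatures(channels=(8, 16, 16))
        )
        vacc = history[-1].val_acc
        se = np.sqrt((1 / 7) * (6 / 7) / 14)
        assert vacc <= 1 / 7 + 3 * se


class TestTrainAndExperiment:
    def test_metrics_recorded_each_epoch(self, rng):
        feats = rng.normal(size=(70, 5))
        labels = np.repeat(np.arange(7), 10)
        cfg = TrainConfig(epochs=12, seed=1)
        clf, history = train(feats, labels, cfg, backbone=_identity_backbone)
        assert [m.epoch for m in history] == list(range(1, 13))
        assert all(0 <= m.val_acc <= 1 for m in history)
        assert all(m.train_loss >= 0 for m in history)

    def test_identical_variants_give_identical_columns(self, rng):
        feats = rng.normal(size=(35, 4))
        labels = np.tile(np.arange(7), 5)
        cfg = TrainConfig(epochs=10, report_epochs=(5, 10))
        table = run_experiment(
            {"a": feats, "b": feats.copy()}, labels, cfg, seeds=(0, 1),
            backbone=_identity_backbone,
        )
        a = table[table.variant == "a"].drop(columns="variant").reset_index(drop=True)
        b = table[table.variant == "b"].drop(columns="variant").reset_index(drop=True)
        assert a.equals(b)
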