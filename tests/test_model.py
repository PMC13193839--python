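import time

import numpy as np
import pytest

from lungct.errors import ConfigurationError, ValidationError
from lungct.model import (
    EarlyStopping,
    ModelConfig,
    TrainConfig,
    build_model,
    predict,
    train,
)


class TestArchitecture:
    def test_default_head_widths_follow_the_published_interface(self):
        cfg = ModelConfig()
        assert cfg.head_widths == (1024, 512, 256, 256, 128, 3)

    def test_probabilities_normalize(self):
        model = build_model(ModelConfig.toy(), seed=0)
        rng = np.random.default_rng(0)
        probs = model.predict_proba(rng.random((4, 224, 224, 3)).astype(np.float32))
        assert probs.shape == (4, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_toy_configuration_builds_and_runs_quickly(self):
        t0 = time.time()
        model = build_model(
            ModelConfig(feature_dim=32, gru_units=(8, 4), dense_units=(16, 8)), seed=0
        )
        model.predict_proba(np.zeros((1, 224, 224, 3), dtype=np.float32))
        assert time.time() - t0 < 1.0

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(backbone="resnet999")

    def test_dense_head_ablation_keeps_widths(self):
        model = build_model(ModelConfig.toy(use_bigru_head=False), seed=0)
        probs = model.predict_proba(np.zeros((2, 224, 224, 3), dtype=np.float32))
        assert probs.shape == (2, 3)


class TestExtractFeatures:
    def test_feature_matrix_shape(self):
        model = build_model(ModelConfig.toy(feature_dim=64), seed=0)
        rng = np.random.default_rng(1)
        feats = model.extract_features(rng.random((5, 224, 224, 3)).astype(np.float32))
        assert feats.shape == (5, 64)

    def test_default_feature_width_is_1024(self):
        model = build_model(ModelConfig(), seed=0)
        feats = model.extract_features(np.zeros((2, 224, 224, 3), dtype=np.float32))
        assert feats.shape == (2, 1024)

    def test_identical_inputs_give_identical_rows(self):
        model = build_model(ModelConfig.toy(), seed=0)
        rng = np.random.default_rng(2)
        img = rng.random((224, 224, 3)).astype(np.float32)
        feats = model.extract_features(np.stack([img, img]))
        assert np.array_equal(feats[0], feats[1])

    def test_distinct_phantoms_give_distinct_rows(self, phantom_spec):
        from lungct.image_core import to_backbone_input
        from lungct.phantom import generate_phantom

        model = build_model(ModelConfig.toy(), seed=0)
        a = to_backbone_input(generate_phantom(phantom_spec, "Normal", seed=0).image)
        b = to_backbone_input(generate_phantom(phantom_spec, "Malignant", seed=0).image)
        feats = model.extract_features(np.stack([a, b]))
        assert not np.array_equal(feats[0], feats[1])

    def test_wrong_input_shape_rejected(self):
        model = build_model(ModelConfig.toy(), seed=0)
        with pytest.raises(ValidationError):
            model.extract_features(np.zeros((1, 64, 64, 3), dtype=np.float32))


class TestEarlyStopping:
    def test_monotone_worsening_after_best_stops_at_patience(self):
        """Best at epoch 2, strictly increasing after: stop at epoch 7."""
        stopper = EarlyStopping(patience=5)
        losses = {1: 1.0, 2: 0.5, 3: 0.6, 4: 0.7, 5: 0.8, 6: 0.9, 7: 1.0}
        stopped_at = None
        for epoch in sorted(losses):
            if stopper.update(epoch, losses[epoch]):
                stopped_at = epoch
                break
        assert stopped_at == 7
        assert stopper.best_epoch == 2

    def test_improvement_resets_patience(self):
        stopper = EarlyStopping(patience=2)
        seq = [(1, 1.0), (2, 1.1), (3, 0.9), (4, 1.0), (5, 1.0)]
        stops = [stopper.update(e, l) for e, l in seq]
        assert stops == [False, False, False, False, True]
        assert stopper.best_epoch == 3

    def test_plateau_counts_as_no_improvement(self):
        stopper = EarlyStopping(patience=3)
        stops = [stopper.update(e, 0.5) for e in range(1, 5)]
        assert stops == [False, False, False, True]


def _tiny_run(seed, images, labels):
    model = build_model(ModelConfig.toy(feature_dim=16, gru_units=(4, 2),
                                        dense_units=(8, 4)), seed=seed)
    tcfg = TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=3, patience=2,
                       freeze_policy="none", seed=seed)
    history = train(model, images, labels, images[:3], labels[:3], tcfg, aug=None)
    return model, history


@pytest.fixture(scope="module")
def noise_images():
    rng = np.random.default_rng(0)
    images = [rng.integers(0, 256, (224, 224)).astype(np.uint8) for _ in range(9)]
    labels = ["Benign", "Malignant", "Normal"] * 3
    return images, labels


class TestTraining:
    def test_history_lengths_match_stopped_epoch(self, noise_images):
        images, labels = noise_images
        _, history = _tiny_run(0, images, labels)
        assert len(history.train_loss) == history.stopped_epoch
        assert len(history.val_loss) == history.stopped_epoch
        assert 1 <= history.best_epoch <= history.stopped_epoch

    def test_repeated_runs_are_identical(self, noise_images):
        images, labels = noise_images
        _, h1 = _tiny_run(3, images, labels)
        _, h2 = _tiny_run(3, images, labels)
        assert h1.to_dict() == h2.to_dict()

    def test_freeze_policy_pins_early_backbone_blocks(self, noise_images):
        images, labels = noise_images
        model = build_model(ModelConfig.toy(), seed=0)
        model.apply_freeze_policy("all_but_last_block")
        frozen_slices = model._block_slices[:-1]
        before = {
            (li, name): model.net.layers[li].params[name].copy()
            for start, stop in frozen_slices
            for li in range(start, stop)
            for name in model.net.layers[li].params
        }
        last_conv_li = model._block_slices[-1][0]
        last_before = model.net.layers[last_conv_li].params["W"].copy()
        tcfg = TrainConfig(learning_rate=1e-2, batch_size=4, max_epochs=2,
                           patience=1, freeze_policy="all_but_last_block", seed=0)
        train(model, images, labels, images[:3], labels[:3], tcfg, aug=None)
        for (li, name), value in before.items():
            assert np.array_equal(model.net.layers[li].params[name], value), (li, name)
        assert not np.array_equal(model.net.layers[last_conv_li].params["W"], last_before)

    def test_empty_training_set_rejected(self):
        model = build_model(ModelConfig.toy(), seed=0)
        with pytest.raises(ValidationError):
            train(model, [], [], [], [], TrainConfig(seed=0), aug=None)


def test_checkpoint_round_trip_preserves_predictions(tmp_path):
    rng = np.random.default_rng(0)
    batch = rng.random((3, 224, 224, 3)).astype(np.float32)
    saved = build_model(ModelConfig.toy(), seed=1)
    path = tmp_path / "ckpt.npz"
    saved.save_weights(path)
    loaded = build_model(ModelConfig.toy(), seed=2)  # different init
    assert not np.allclose(loaded.predict_proba(batch), saved.predict_proba(batch))
    loaded.load_weights(path)
    assert np.array_equal(loaded.predict_proba(batch), saved.predict_proba(batch))


class TestPredict:
    def test_label_count_matches_batch(self, noise_images):
        images, labels = noise_images
        model = build_model(ModelConfig.toy(), seed=0)
        probs, pred = predict(model, images)
        assert probs.shape == (9, 3)
        assert len(pred) == 9

    def test_argmax_maps_to_fixed_class_order(self):
        from lungct.manifest import decode_labels

        assert decode_labels(np.array([[0.2, 0.5, 0.3]]).argmax(axis=1)) == ["Malignant"]
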