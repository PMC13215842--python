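"""Pseudo-image spatialization, model structure, training behaviour."""

import numpy as np
import pytest

from cytofuse import nn
from cytofuse.datatypes import FeatureMatrix
from cytofuse.tcma import (
    TCMAConfig,
    build_model,
    partition_patches,
    predict,
    pseudo_image_batch,
    reassemble_patches,
    standardize,
    to_pseudo_image,
    train,
)


class TestStandardize:
    def test_zscore_identity(self):
        m = FeatureMatrix(np.array([[1.0], [2.0], [3.0]]), ["a", "b", "a"])
        out, _ = standardize(m)
        assert out.values.mean() == pytest.approx(0, abs=1e-12)
        assert out.values.std() == pytest.approx(1, abs=1e-12)

    def test_test_row_at_train_mean_maps_to_zero(self):
        train_m = FeatureMatrix(np.array([[1.0], [3.0]]), ["a", "b"])
        _, state = standardize(train_m)
        test_m = FeatureMatrix(np.array([[2.0]]), ["a"])
        out, _ = standardize(test_m, state)
        assert out.values[0, 0] == pytest.approx(0.0)

    def test_constant_column_zero(self):
        m = FeatureMatrix(np.full((4, 2), 5.0), ["a"] * 4)
        out, _ = standardize(m)
        assert (out.values == 0).all()


class TestPseudoImage:
    def test_d19_geometry(self):
        p = to_pseudo_image(np.arange(19.0))
        assert p.m == 5 and p.pad_count == 6
        assert p.pixels.shape == (32, 32, 1)

    def test_perfect_square_1024_roundtrip_exact(self, rng):
        x = rng.normal(size=1024)
        p = to_pseudo_image(x)
        assert p.m == 32 and p.pad_count == 0
        assert np.array_equal(p.pixels[:, :, 0].ravel(), x)

    def test_zeros_map_to_zeros(self):
        assert (to_pseudo_image(np.zeros(19)).pixels == 0).all()

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            to_pseudo_image(np.array([]))

    def test_batch_matches_single(self, rng):
        X = rng.normal(size=(5, 19))
        batch = pseudo_image_batch(X)
        for i in range(5):
            single = to_pseudo_image(X[i]).pixels
            assert np.allclose(batch[i], single, atol=1e-6)


class TestPatches:
    def test_16_patches_of_side_8(self, rng):
        p = to_pseudo_image(rng.normal(size=1024))
        patches = partition_patches(p)
        assert patches.shape == (16, 64)

    def test_reassembly_exact(self, rng):
        img = rng.normal(size=(32, 32))
        assert np.array_equal(reassemble_patches(partition_patches(img)), img)

    def test_block_constant_patches_constant(self):
        img = np.kron(np.arange(16.0).reshape(4, 4), np.ones((8, 8)))
        patches = partition_patches(img)
        assert all(np.ptp(row) == 0 for row in patches)

    def test_non_divisible_grid_rejected(self):
        with pytest.raises(ValueError):
            partition_patches(np.zeros((32, 32)), grid=5)


class TestModelStructure:
    def test_table_defaults_and_block_widths(self):
        cfg = TCMAConfig(n_classes=4)
        assert cfg.patch_size == 8
        assert cfg.cnn_filters == (32, 64, 128)
        assert cfg.cnn_dense == 256
        assert cfg.batch_size == 64 and cfg.epochs == 100
        assert cfg.learning_rate == pytest.approx(1e-4) and cfg.dropout == 0.2
        model = build_model(cfg)
        convs = [l for l in model.cnn.walk() if isinstance(l, nn.Conv2DSame)]
        assert [c.params["W"].shape[-1] for c in convs] == [32, 32, 64, 64, 128, 128]
        dense = next(l for l in model.cnn_head.walk() if isinstance(l, nn.Dense))
        assert dense.params["W"].shape == (4 * 4 * 128, 256)
        assert model.head.params["W"].shape[-1] == 4

    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(TCMAConfig(n_classes=5, seed=1))
        x = rng.normal(size=(7, 32, 32, 1)).astype(np.float32)
        probs = model.predict_proba(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            TCMAConfig(n_classes=1)

    def test_inference_deterministic_with_duplicates(self, rng):
        model = build_model(TCMAConfig(n_classes=3, seed=2))
        x = rng.normal(size=(2, 32, 32, 1)).astype(np.float32)
        both = np.concatenate([x, x])
        probs = model.predict_proba(both)
        assert np.array_equal(probs[:2], probs[2:])

    def test_argmax_invariant_to_logit_shift(self, rng):
        logits = rng.normal(size=(10, 4))
        assert (
            nn.softmax(logits).argmax(axis=1) == nn.softmax(logits + 7.3).argmax(axis=1)
        ).all()


class TestTraining:
    def _clusters(self, n=120, d=19, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(-2, 1, (n // 2, d)), rng.normal(2, 1, (n - n // 2, d))]
        )
        labels = ["neg"] * (n // 2) + ["pos"] * (n - n // 2)
        return FeatureMatrix(X, labels)

    def test_initial_loss_near_ln_c(self):
        m = self._clusters()
        cfg = TCMAConfig(n_classes=2, epochs=1, learning_rate=0.0, seed=0)
        model = build_model(cfg)
        hist = train(model, m, config=cfg)
        assert hist["loss"][0] == pytest.approx(np.log(2), abs=0.25)

    def test_zero_lr_leaves_parameters_unchanged(self):
        m = self._clusters()
        cfg = TCMAConfig(n_classes=2, epochs=1, learning_rate=0.0, seed=0)
        model = build_model(cfg)
        before = [
            {k: v.copy() for k, v in l.params.items()} for l in model.all_layers()
        ]
        train(model, m, config=cfg)
        for layer, snap in zip(model.all_layers(), before):
            for k in snap:
                assert np.array_equal(layer.params[k], snap[k])

    def test_separable_clusters_learned(self):
        """Two separable feature clusters reach >= 0.99 training accuracy."""
        m = self._clusters()
        cfg = TCMAConfig(n_classes=2, epochs=30, learning_rate=1e-3, seed=0)
        model = build_model(cfg)
        hist = train(model, m, config=cfg)
        assert max(hist["accuracy"]) >= 0.99
        probs, preds = predict(model, m)
        assert np.mean([p == l for p, l in zip(preds, m.labels)]) >= 0.99

    def test_training_reproducible(self):
        m = self._clusters()
        cfg = TCMAConfig(n_classes=2, epochs=2, seed=3)
        h1 = train(build_model(cfg), m, config=cfg)
        h2 = train(build_model(cfg), m, config=cfg)
        assert h1 == h2

    def test_dim_mismatch_at_predict_rejected(self):
        m = self._clusters(d=19)
        cfg = TCMAConfig(n_classes=2, epochs=1, seed=0)
        model = build_model(cfg)
        train(model, m, config=cfg)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, self._clusters(d=25))


class TestPersistence:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        from cytofuse.tcma import load_model, save_model

        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-1, 1, (30, 19)), rng.normal(1, 1, (30, 19))])
        m = FeatureMatrix(X, ["a"] * 30 + ["b"] * 30)
        cfg = TCMAConfig(n_classes=2, epochs=2, seed=5)
        model = build_model(cfg)
        std, state = standardize(m)
        train(model, std, config=cfg)
        probs_before, _ = predict(model, std)
        save_model(model, tmp_path, scaler=state)
        restored, scaler = load_model(tmp_path)
        restd, _ = standardize(m, scaler)
        probs_after, _ = predict(restored, restd)
        assert np.array_equal(probs_before, probs_after)
        assert restored.class_map == model.class_map
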