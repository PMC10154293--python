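"""Network correctness: gradient checks, structure, sampling, augmentation,
and the training loop's early-stopping behaviour."""

import numpy as np
import pytest

import ductseg as ds
import ductseg.nn.layers as L
from ductseg.nn.training import EarlyStopper
from ductseg.nn.unet import ModelConfig, build_model


def _numeric_grad_check(rng, n_checks=4, eps=1e-6):
    """Central-difference check of the full forward/backward in float64."""
    old = L.F32
    L.F32 = np.float64
    try:
        model = build_model(ModelConfig(input_size=16, depth=2, base_filters=2, seed=3))
        x = rng.random((2, 16, 16, 3))
        y = np.zeros((2, 16, 16, 3))
        idx = rng.integers(0, 3, size=(2, 16, 16))
        for c in range(3):
            y[..., c][idx == c] = 1

        def loss_fn():
            probs = L.softmax_channels(model.forward(x, train=True))
            return L.cross_entropy(probs, y)

        _, dlogits = loss_fn()
        for p in model.params():
            p.grad[...] = 0
        model.backward(dlogits)
        failures = []
        for p in model.params():
            flat, g = p.value.ravel(), p.grad.ravel()
            for k in rng.choice(flat.size, size=min(n_checks, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = loss_fn()
                flat[k] = orig - eps
                lm, _ = loss_fn()
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                # conv biases feeding a batch norm have an exactly-zero gradient;
                # only flag real disagreements
                if max(abs(num), abs(g[k])) < 1e-7:
                    continue
                rel = abs(num - g[k]) / max(abs(num), abs(g[k]))
                if rel > 1e-4:
                    failures.append((p.name, k, num, g[k], rel))
        return failures
    finally:
        L.F32 = old


def test_backprop_matches_numerical_gradients():
    failures = _numeric_grad_check(np.random.default_rng(0))
    assert not failures, failures


class TestArchitecture:
    def test_softmax_normalization_on_untrained_model(self, tiny_model):
        x = np.random.default_rng(1).random((2, 32, 32, 3), dtype=np.float32)
        probs = tiny_model.predict_proba(x)
        assert probs.shape == (2, 32, 32, 3)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_default_filter_progression_reaches_64(self):
        cfg = ModelConfig()
        assert cfg.encoder_filters == (4, 8, 16, 32, 64)
        model = build_model(cfg)
        deepest = model.bottleneck.ops[3]  # second conv of the bottleneck block
        assert deepest.c_out == 64

    def test_indivisible_input_size_raises(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((1, 31, 31, 3), dtype=np.float32))

    def test_invalid_model_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=127)

    def test_constant_input_gives_near_uniform_interior_prediction(self, tiny_model):
        x = np.full((1, 32, 32, 3), 0.5, dtype=np.float32)
        probs = tiny_model.predict_proba(x)[0]
        interior = probs[8:-8, 8:-8]
        spread = interior.max(axis=(0, 1)) - interior.min(axis=(0, 1))
        assert (spread < 0.2).all()

    def test_state_dict_round_trip(self, tmp_path):
        cfg = ModelConfig(input_size=32, depth=2, base_filters=2, seed=4)
        model = build_model(cfg)
        path = tmp_path / "weights.npz"
        model.save(path)
        clone = ds.AttentionUNet.load(path, cfg)
        x = np.random.default_rng(2).random((1, 32, 32, 3), dtype=np.float32)
        assert np.array_equal(model.predict_proba(x), clone.predict_proba(x))


class TestSamplePatches:
    def _data(self):
        spec = ds.CoreSpec(height_px=160, ring_widths_px=(150, 150),
                           duct_count_per_ring=(2, 2), seed=3)
        image, gt = ds.generate_core(spec)
        return image, ds.rasterize(gt, image.shape[:2])

    def test_returns_requested_count_with_foreground(self):
        image, mask = self._data()
        cfg = ds.TrainConfig(patches_per_image=25, seed=0)
        pairs = ds.sample_patches(image, mask, cfg)
        assert len(pairs) == 25
        for img_p, mask_p in pairs:
            assert img_p.shape == (128, 128, 3) and mask_p.shape == (128, 128)
            assert mask_p.max() >= 1

    def test_seed_reproducible(self):
        image, mask = self._data()
        cfg = ds.TrainConfig(patches_per_image=10, seed=5)
        a = ds.sample_patches(image, mask, cfg)
        b = ds.sample_patches(image, mask, cfg)
        for (ia, ma), (ib, mb) in zip(a, b):
            assert np.array_equal(ia, ib) and np.array_equal(ma, mb)

    def test_image_smaller_than_patch_raises(self):
        cfg = ds.TrainConfig(patches_per_image=1)
        with pytest.raises(ValueError):
            ds.sample_patches(np.zeros((64, 64, 3)), np.zeros((64, 64), np.uint8), cfg)

    def test_all_background_mask_raises(self):
        cfg = ds.TrainConfig(patches_per_image=1)
        with pytest.raises(ValueError, match="foreground"):
            ds.sample_patches(np.zeros((128, 200, 3)), np.zeros((128, 200), np.uint8), cfg)


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64, 3)).astype(np.float32)
        mask = (rng.random((64, 64)) < 0.1).astype(np.uint8) * 2
        return img, mask

    def test_disabled_is_identity(self):
        img, mask = self._pair()
        out_img, out_mask = ds.augment((img, mask), 0, enabled=False)
        assert np.array_equal(out_img, img) and np.array_equal(out_mask, mask)

    def test_flip_twice_is_identity(self):
        img, mask = self._pair()
        flipped = (img[:, ::-1].copy(), mask[:, ::-1].copy())
        again = (flipped[0][:, ::-1], flipped[1][:, ::-1])
        assert np.array_equal(again[0], img) and np.array_equal(again[1], mask)

    def test_mask_labels_preserved_by_nearest_neighbour(self):
        img, mask = self._pair()
        for seed in range(8):
            _, out_mask = ds.augment((img, mask), seed)
            assert set(np.unique(out_mask)) <= set(np.unique(mask))

    def test_same_transform_hits_both_members(self):
        # encode the mask into an image channel; the two must stay aligned
        img, mask = self._pair()
        img2 = img.copy()
        img2[..., 0] = mask
        out_img, out_mask = ds.augment((img2, mask), 3)
        # nearest vs linear interpolation differ off grid, so compare support loosely
        assert (out_img[..., 0] > 0.5).sum() == pytest.approx((out_mask > 0).sum(), rel=0.2)


class TestEarlyStopping:
    def test_monotonically_worsening_stops_after_patience(self):
        stopper = EarlyStopper(patience=10)
        epochs_run = 0
        for epoch in range(1, 100):
            epochs_run = epoch
            if stopper.update(1.0 + 0.1 * epoch, epoch):
                break
        assert epochs_run == 11
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = EarlyStopper(patience=2)
        assert not stopper.update(1.0, 1)
        assert not stopper.update(1.1, 2)
        assert not stopper.update(0.9, 3)
        assert not stopper.update(1.0, 4)
        assert stopper.update(1.0, 5)
        assert stopper.best_epoch == 3


class TestTrainLoop:
    def test_empty_patch_set_raises(self, tiny_model):
        with pytest.raises(ValueError):
            ds.train(tiny_model, [], ds.TrainConfig())

    def test_smoke_training_reduces_loss_and_records_history(self):
        rng = np.random.default_rng(0)
        cfg = ds.ModelConfig(input_size=32, depth=2, base_filters=2, seed=1)
        model = ds.build_model(cfg)
        # trivially learnable patches: bright disk-ish blobs labelled duct
        pairs = []
        for _ in range(24):
            mask = np.zeros((32, 32), dtype=np.uint8)
            r, c = rng.integers(8, 24, size=2)
            mask[r - 4:r + 4, c - 4:c + 4] = 2
            img = np.repeat((mask == 2)[..., None].astype(np.float32), 3, axis=-1)
            pairs.append((img, mask))
        tcfg = ds.TrainConfig(patches_per_image=1, patch_size=32, max_epochs=5,
                              patience=10, batch_size=8, augment_enabled=False, seed=0)
        _, history = ds.train(model, pairs, tcfg)
        assert len(history["train_loss"]) == len(history["val_loss"]) == 5
        assert history["train_loss"][-1] < history["train_loss"][0]


def test_overfit_capacity_on_small_patch_set():
    """Trained on a handful of patches, the net must fit them almost exactly."""
    spec = ds.CoreSpec(height_px=128, ring_widths_px=(90, 110),
                       duct_count_per_ring=(2, 2), noise_sd=0.01, seed=11)
    image, gt = ds.generate_core(spec)
    mask = ds.rasterize(gt, image.shape[:2])
    cfg = ds.TrainConfig(patches_per_image=32, patch_size=64, max_epochs=120,
                         patience=120, batch_size=8, augment_enabled=False,
                         learning_rate=5e-3, seed=0)
    pairs = ds.sample_patches(image, mask, cfg)
    model = ds.build_model(ds.ModelConfig(input_size=64, seed=0))
    model, _ = ds.train(model, pairs, cfg)
    imgs = np.stack([p for p, _ in pairs])
    masks = np.stack([m for _, m in pairs])
    probs = np.concatenate([model.predict_proba(imgs[i:i + 8]) for i in range(0, 32, 8)])
    pred = probs.argmax(axis=-1)
    # channel order (ring, duct, background) -> labels (1, 2, 0)
    pred_labels = np.choose(pred, [1, 2, 0])
    accuracy = (pred_labels == masks).mean()
    assert accuracy > 0.95
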