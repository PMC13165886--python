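"""Model assembly: ablation identities, loss contract, training mechanics."""

import numpy as np
import pytest

from structseg.mini_segmenter import (MiniSegmenter, ModelConfig, SegmenterNetwork,
                                      TrainConfig, combined_loss, load_checkpoint,
                                      masks_from_logits, predict_masks,
                                      save_checkpoint, train_segmenter)
from conftest import small_estimator


def _images(rng, n=2, size=48, ch=3):
    return rng.random((n, ch, size, size))


class TestForwardIdentities:
    def test_every_toggle_inert_at_init(self, small_config, rng):
        """A fresh model yields bitwise-identical logits under all 2³
        toggle combinations (zero-init residual contracts)."""
        imgs = _images(rng)
        base = None
        for fg in (False, True):
            for pc in (False, True):
                for sc in (False, True):
                    cfg = ModelConfig(**{**small_config.__dict__,
                                         "fine_grained": fg,
                                         "prompt_confidence": pc, "scfd": sc})
                    out = SegmenterNetwork(cfg).forward(imgs).data
                    if base is None:
                        base = out
                    else:
                        np.testing.assert_array_equal(out, base)

    def test_deterministic_repeat(self, small_net, rng):
        imgs = _images(rng)
        np.testing.assert_array_equal(small_net.forward(imgs).data,
                                      small_net.forward(imgs).data)

    def test_same_seed_same_weights_same_logits(self, small_config, rng):
        imgs = _images(rng)
        a = SegmenterNetwork(small_config).forward(imgs).data
        b = SegmenterNetwork(small_config).forward(imgs).data
        np.testing.assert_array_equal(a, b)

    def test_wrong_shape_raises(self, small_net, rng):
        with pytest.raises(ValueError):
            small_net.forward(rng.random((1, 3, 32, 32)))


class TestCombinedLoss:
    def test_perfect_prediction_near_zero(self):
        labels = np.zeros((1, 4, 4), dtype=int)
        labels[0, :2] = 1
        logits = np.full((1, 2, 4, 4), -20.0)
        logits[0, 0][labels[0] == 0] = 20.0
        logits[0, 1][labels[0] == 1] = 20.0
        assert float(np.asarray(combined_loss(logits, labels, beta=0.8))) <= 1e-3

    def test_hand_dice_oracle_2x2(self):
        """Uniform 0.5 probabilities, half-foreground labels: soft Dice
        2·Σpg/(Σp+Σg) computed by hand."""
        labels = np.array([[[0, 1], [0, 1]]])
        logits = np.zeros((1, 2, 2, 2))  # softmax → 0.5 everywhere
        eps = 1e-5
        # foreground: Σp=2, Σg=2, Σpg=1 → dice=(2+eps)/(4+eps)
        want_dice_loss = 1 - (2 * 1 + eps) / (2 + 2 + eps)
        want_ce = -np.log(0.5)
        want = 0.2 * want_ce + 0.8 * want_dice_loss
        got = float(np.asarray(combined_loss(logits, labels, beta=0.8, eps=eps)))
        assert got == pytest.approx(want, rel=1e-6)

    def test_degrades_with_mask_perturbation(self):
        rng = np.random.default_rng(0)
        labels = np.zeros((1, 8, 8), dtype=int)
        labels[0, 2:6, 2:6] = 1
        losses = []
        for flip in (0, 4, 12):
            pred = labels.copy()
            idx = rng.choice(64, size=flip, replace=False)
            pred.reshape(1, -1)[0, idx] = 1 - pred.reshape(1, -1)[0, idx]
            logits = np.where(np.eye(2)[pred].transpose(0, 3, 1, 2) > 0, 15.0, -15.0)
            losses.append(float(np.asarray(combined_loss(logits, labels))))
        assert losses[0] < losses[1] < losses[2]

    def test_validation(self):
        logits = np.zeros((1, 2, 2, 2))
        with pytest.raises(ValueError):
            combined_loss(logits, np.full((1, 2, 2), 5), beta=0.8)
        with pytest.raises(ValueError):
            combined_loss(logits, np.zeros((1, 2, 2), dtype=int), beta=1.2)


class TestPredict:
    def test_uniform_winner(self):
        logits = np.zeros((1, 3, 2, 2))
        logits[:, 1] = 5.0
        np.testing.assert_array_equal(masks_from_logits(logits), 1)

    def test_tie_breaks_to_lower_class(self):
        logits = np.zeros((1, 3, 2, 2))
        logits[:, 0] = 1.0
        logits[:, 2] = 1.0
        np.testing.assert_array_equal(masks_from_logits(logits), 0)

    def test_matches_per_pixel_argmax(self, rng):
        logits = rng.normal(size=(2, 4, 3, 3))
        got = masks_from_logits(logits)
        for b in range(2):
            for i in range(3):
                for j in range(3):
                    assert got[b, i, j] == np.argmax(logits[b, :, i, j])


class TestTraining:
    def test_loss_decreases_on_small_set(self, tiny_fundus_suite):
        X, y = tiny_fundus_suite.arrays(0)
        decreased = 0
        for seed in (0, 1, 2):
            est = small_estimator(max_epochs=7, seed=seed, batch_size=4)
            est.fit(X, y)
            if est.history_[-1]["loss"] < est.history_[0]["loss"]:
                decreased += 1
        assert decreased == 3

    def test_training_is_seed_deterministic(self, tiny_fundus_suite):
        X, y = tiny_fundus_suite.arrays(0)
        h = []
        for _ in range(2):
            est = small_estimator(max_epochs=2, seed=5, batch_size=4)
            est.fit(X, y)
            h.append(est.history_)
        assert h[0] == h[1]

    def test_frozen_backbone_bits_unchanged(self, tiny_fundus_suite):
        X, y = tiny_fundus_suite.arrays(0)
        est = small_estimator(max_epochs=1, batch_size=4, frozen_backbone=True)
        net = SegmenterNetwork(est.model_config())
        before = [p.data.copy() for p in net.parameters()]
        train_segmenter(net, est._to_chw(X, 3), y, est.train_config())
        head_moved = False
        for p, b in zip(net.parameters(), before):
            if p.group == "backbone":
                np.testing.assert_array_equal(p.data, b)
            elif not np.array_equal(p.data, b):
                head_moved = True
        assert head_moved  # the trainable stack did update

    def test_empty_dataset_raises(self, small_config):
        net = SegmenterNetwork(small_config)
        with pytest.raises(ValueError):
            train_segmenter(net, np.zeros((0, 3, 48, 48)), np.zeros((0, 48, 48)),
                            TrainConfig())


def test_checkpoint_roundtrip(tmp_path, small_config, rng):
    net = SegmenterNetwork(small_config)
    for p in net.parameters():
        p.data = p.data + rng.normal(0, 0.01, p.data.shape).astype(p.data.dtype)
    path = tmp_path / "model.npz"
    save_checkpoint(net, path)
    net2 = load_checkpoint(path)
    imgs = _images(rng)
    np.testing.assert_array_equal(net.forward(imgs).data, net2.forward(imgs).data)


def test_estimator_sklearn_contract(tiny_fundus_suite):
    from sklearn.base import clone
    est = small_estimator(max_epochs=1, batch_size=4)
    est2 = clone(est)
    assert est2.get_params() == est.get_params()
    X, y = tiny_fundus_suite.arrays(0)
    est2.fit(X, y)
    preds = est2.predict(X)
    assert preds.shape == y.shape and preds.dtype.kind in "iu"
    assert 0.0 <= est2.score(X, y) <= 1.0
    conf = est2.confidence_scores(X[:4])
    assert conf.shape == (4,) and np.all((conf >= 0) & (conf <= 1))
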