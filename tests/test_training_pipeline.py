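import numpy as np
import pytest

from lesionseg.architecture import ModelConfig, build_model
from lesionseg.synthetic_data import SceneSpec, make_dataset
from lesionseg.training_pipeline import (
    TrainConfig,
    contour_overlay,
    evaluate,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)

TINY = ModelConfig(input_size=32, filter_ladder=(2, 4, 4, 4))


def tiny_dataset(n, seed=0):
    data = make_dataset(n, SceneSpec(size=32), seed=seed)
    return [(im.astype(np.float32), mk) for im, mk in data]


class TestTrain:
    def test_history_length(self):
        model = build_model(TINY, seed=0)
        _, hist = train(model, tiny_dataset(4), TrainConfig(epochs=1, batch_size=2))
        assert len(hist.loss) == 1
        assert len(hist.accuracy) == 1

    def test_seeded_epoch1_loss_reproducible(self):
        losses = []
        for _ in range(2):
            model = build_model(TINY, seed=7)
            _, hist = train(
                model, tiny_dataset(4), TrainConfig(epochs=1, batch_size=2, seed=7)
            )
            losses.append(hist.loss[0])
        assert losses[0] == pytest.approx(losses[1], abs=1e-9)

    def test_loss_decreases(self):
        model = build_model(TINY, seed=1)
        _, hist = train(
            model, tiny_dataset(8), TrainConfig(epochs=8, batch_size=4, seed=1)
        )
        assert hist.loss[-1] < hist.loss[0]

    def test_descent_across_seeds(self):
        # final < initial loss in >= 90% of seeded runs
        wins = 0
        for seed in range(5):
            model = build_model(TINY, seed=seed)
            _, hist = train(
                model,
                tiny_dataset(8, seed=seed),
                TrainConfig(epochs=4, batch_size=4, seed=seed),
            )
            wins += hist.loss[-1] < hist.loss[0]
        assert wins >= 5 * 0.9

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(TINY, seed=0), [], TrainConfig(epochs=1))

    def test_shape_mismatch_rejected(self):
        data = make_dataset(2, SceneSpec(size=64), seed=0)
        with pytest.raises(ValueError):
            train(build_model(TINY, seed=0), data, TrainConfig(epochs=1))

    def test_nan_loss_aborts_with_diagnostic(self):
        model = build_model(TINY, seed=0)
        for p in model.parameters():
            p.data[:] = np.nan
        with pytest.raises(FloatingPointError):
            train(model, tiny_dataset(2), TrainConfig(epochs=1, batch_size=2))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"learning_rate": 0.0},
            {"epochs": 0},
            {"threshold": 1.0},
            {"loss": "hinge"},
            {"optimizer": "sgd"},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)

    def test_paper_defaults(self):
        cfg = TrainConfig()
        assert cfg.optimizer == "adam"
        assert cfg.learning_rate == 0.001
        assert cfg.epochs == 150


class TestPredict:
    def test_untrained_model_deterministic(self):
        data = tiny_dataset(1)
        a = predict(build_model(TINY, seed=3), data[0][0])
        b = predict(build_model(TINY, seed=3), data[0][0])
        np.testing.assert_array_equal(a, b)

    def test_threshold_extremes(self):
        image = tiny_dataset(1)[0][0]
        model = build_model(TINY, seed=0)
        assert predict(model, image, threshold=0.0).all()  # sigmoid strictly > 0
        assert not predict(model, image, threshold=1.0).any()


class _OracleModel:
    """Duck-typed stand-in whose probabilities are the ground truth."""

    def __init__(self, lookup):
        self.lookup = lookup

    def predict_proba(self, images):
        images = np.asarray(images)
        if images.ndim == 3:
            return self.lookup[images.tobytes()].astype(float)
        return np.stack(
            [self.lookup[np.asarray(im).tobytes()].astype(float) for im in images]
        )


class TestEvaluate:
    def test_perfect_oracle_scores_one(self):
        data = tiny_dataset(3)
        lookup = {im.tobytes(): mk for im, mk in data}
        report = evaluate(_OracleModel(lookup), data)
        assert report.dice == 1.0
        assert report.jaccard == 1.0
        assert report.accuracy == 1.0

    def test_report_carries_mode(self):
        data = tiny_dataset(2)
        lookup = {im.tobytes(): mk for im, mk in data}
        for mode in ("none", "micro", "macro"):
            assert evaluate(_OracleModel(lookup), data, mode=mode).averaging_mode == mode

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            evaluate(build_model(TINY, seed=0), [])


class TestContourOverlay:
    def test_empty_mask_unchanged(self, rng):
        image = rng.random((16, 16, 3))
        np.testing.assert_array_equal(
            contour_overlay(image, np.zeros((16, 16), dtype=int)), image
        )

    def test_full_mask_draws_frame_border(self, rng):
        image = rng.random((8, 8, 3)) * 0.5
        out = contour_overlay(image, np.ones((8, 8), dtype=int))
        assert (out[0] == [1.0, 0.0, 0.0]).all()
        assert (out[-1] == [1.0, 0.0, 0.0]).all()
        np.testing.assert_array_equal(out[1:-1, 1:-1], image[1:-1, 1:-1])

    def test_circle_mask_touches_boundary_only(self, rng):
        from skimage.draw import disk as draw_disk

        image = rng.random((32, 32, 3)) * 0.5
        mask = np.zeros((32, 32), dtype=int)
        rr, cc = draw_disk((16, 16), 8)
        mask[rr, cc] = 1
        out = contour_overlay(image, mask)
        changed = np.argwhere((out != image).any(-1))
        from skimage.segmentation import find_boundaries

        boundary = np.argwhere(find_boundaries(mask.astype(bool), mode="inner"))
        assert set(map(tuple, changed)) <= set(map(tuple, boundary))
        assert len(changed) > 0


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        model = build_model(TINY, seed=4)
        image = tiny_dataset(1)[0][0]
        before = model.predict_proba(image)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        restored = load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_allclose(restored.predict_proba(image), before, atol=1e-7)
        assert restored.config == model.config

    def test_best_loss_checkpoint_written(self, tmp_path):
        model = build_model(TINY, seed=0)
        cfg = TrainConfig(
            epochs=2, batch_size=2, checkpoint_path=str(tmp_path / "best.npz")
        )
        train(model, tiny_dataset(2), cfg)
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "best.json").exists()
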