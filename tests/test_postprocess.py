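"""Thresholding, grid search, TTA, ensembling and submission writing."""

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label

from pneumoseg.postprocess import (
    ENSEMBLE_PRESETS,
    EnsembleConfig,
    ThresholdConfig,
    apply_thresholds,
    binarize,
    ensemble_average,
    predict_masks,
    remove_small,
    threshold_grid,
    tta_predict,
    tune_thresholds,
    write_submission,
)
from pneumoseg.rle import decode_rle, load_annotations
from pneumoseg.synthetic import PhantomConfig, generate_corpus, generate_probability_maps
from pneumoseg.unet import build_bunet


class TestBinarize:
    def test_strict_boundary(self):
        assert binarize(np.array([[0.74]]), 0.73)[0, 0] == 1
        assert binarize(np.array([[0.73]]), 0.73)[0, 0] == 0  # P <= B-TH -> 0

    def test_uniform_below(self):
        assert binarize(np.full((8, 8), 0.4), 0.5).sum() == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 1.5)


class TestRemoveSmall:
    def make_components(self):
        mask = np.zeros((80, 80), dtype=np.uint8)
        mask[:10, :10] = 1  # 100 px
        mask[20:80, 20:70] = 1  # 3000 px
        return mask

    def test_exactly_r_th_erased_strictly_larger_kept(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[:4, :4] = 1  # 16 pixels
        assert remove_small(mask, 16).sum() == 0  # == r_th -> erased
        assert remove_small(mask, 15).sum() == 16  # > r_th -> kept

    def test_component_mode_keeps_large_only(self):
        out = remove_small(self.make_components(), 1024, "component")
        assert out.sum() == 3000
        assert label(out, connectivity=2).max() == 1

    def test_whole_mask_mode(self):
        mask = self.make_components()  # total 3100
        assert remove_small(mask, 1024, "whole_mask").sum() == 3100
        assert remove_small(mask, 4096, "whole_mask").sum() == 0

    def test_idempotent(self, rng):
        mask = (rng.random((64, 64)) < 0.3).astype(np.uint8)
        once = remove_small(mask, 20)
        np.testing.assert_array_equal(remove_small(once, 20), once)

    def test_eight_connectivity(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = 1  # one diagonal component
        assert remove_small(mask, 2).sum() == 3
        assert remove_small(mask, 3).sum() == 0


class TestThresholdGrid:
    def test_b_th_candidates(self):
        grid = threshold_grid()
        b_values = sorted({cfg.b_th for cfg in grid})
        assert len(b_values) == 70
        assert b_values[0] == 0.20
        assert b_values[-1] == 0.89
        assert b_values[1] == 0.21

    def test_r_th_candidates_and_product(self):
        grid = threshold_grid()
        r_values = {cfg.r_th for cfg in grid}
        assert r_values == {None, 1024, 2048, 3072, 4096}
        assert len(grid) == 350


class TestTuneThresholds:
    def test_planted_threshold_recovery(self):
        """Truths made by binarizing the maps at 0.42 are recovered at the
        planted grid point (or its lower neighbor under strict inequality)."""
        rng = np.random.default_rng(7)
        maps = [rng.random((48, 48)) for _ in range(6)]
        truths = [binarize(m, 0.42) for m in maps]
        best, table = tune_thresholds(maps, truths)
        assert best.b_th in (0.41, 0.42)
        assert best.r_th is None

    def test_all_empty_ties_break_least_aggressive(self):
        maps = [np.zeros((16, 16)) for _ in range(3)]
        truths = [np.zeros((16, 16), dtype=np.uint8) for _ in range(3)]
        best, table = tune_thresholds(maps, truths)
        assert best.b_th == 0.20
        assert best.r_th is None
        assert (table.score == 1.0).all()

    def test_score_table_one_row_per_grid_point(self):
        maps = [np.random.default_rng(0).random((16, 16))]
        truths = [binarize(maps[0], 0.5)]
        _, table = tune_thresholds(maps, truths)
        assert len(table) == 350
        assert not table.duplicated(["b_th", "r_th"]).any()

    def test_empty_validation_set(self):
        with pytest.raises(ValueError):
            tune_thresholds([], [])


def test_monotone_foreground_in_b_th(rng):
    prob = rng.random((64, 64))
    counts = [binarize(prob, b).sum() for b in np.linspace(0.05, 0.95, 19)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, image):
        return np.full(image.shape[:2], self.value)


class TestTta:
    def test_constant_model_passthrough(self, rng):
        out = tta_predict(_ConstantModel(0.3), rng.random((32, 32, 3)))
        np.testing.assert_allclose(out, 0.3)

    def test_symmetric_input_gives_symmetric_map(self, rng):
        net = build_bunet("tiny_unet", seed=1)
        half = rng.random((64, 32, 3)).astype(np.float32)
        image = np.concatenate([half, half[:, ::-1]], axis=1)
        out = tta_predict(net, image)
        np.testing.assert_allclose(out, out[:, ::-1], atol=1e-6)

    def test_within_member_envelope(self, rng):
        net = build_bunet("tiny_unet", seed=2)
        image = rng.random((64, 64, 3)).astype(np.float32)
        a = net.predict(image)
        b = net.predict(image[:, ::-1, :])[:, ::-1]
        out = tta_predict(net, image)
        assert (out >= np.minimum(a, b) - 1e-9).all()
        assert (out <= np.maximum(a, b) + 1e-9).all()


class TestEnsemble:
    def test_identical_maps_any_weights(self, rng):
        m = rng.random((16, 16))
        cfg = EnsembleConfig([("a", 0.7), ("b", 0.1), ("c", 0.2)])
        np.testing.assert_allclose(ensemble_average([m, m, m], cfg), m)

    def test_equal_weights_midpoint(self):
        cfg = EnsembleConfig([("a", 1.0), ("b", 1.0)])
        out = ensemble_average([np.zeros((4, 4)), np.ones((4, 4))], cfg)
        np.testing.assert_allclose(out, 0.5)

    def test_published_weights_normalize(self):
        cfg = ENSEMBLE_PRESETS["prose_40_40_20_20"]
        np.testing.assert_allclose(cfg.weights, [1 / 3, 1 / 3, 1 / 6, 1 / 6])
        assert cfg.weights.sum() == pytest.approx(1.0)
        table = ENSEMBLE_PRESETS["table_10_10_40_40"]
        np.testing.assert_allclose(table.weights, [0.4, 0.4, 0.1, 0.1])

    def test_errors(self):
        with pytest.raises(ValueError):
            EnsembleConfig([("a", -0.1)])
        with pytest.raises(ValueError):
            EnsembleConfig([])
        cfg = EnsembleConfig([("a", 1.0), ("b", 1.0)])
        with pytest.raises(ValueError):
            ensemble_average([np.zeros((4, 4))], cfg)
        with pytest.raises(ValueError):
            ensemble_average([np.zeros((4, 4)), np.zeros((5, 5))], cfg)


class TestSubmission:
    def test_rows_roundtrip(self, tmp_path, rng):
        mask = (rng.random((64, 64)) < 0.1).astype(np.uint8)
        empty = np.zeros((64, 64), dtype=np.uint8)
        path = write_submission([("img1", mask), ("img2", empty)], tmp_path / "sub.csv")
        df = pd.read_csv(path, dtype=str)
        assert list(df.columns) == ["ImageId", "EncodedPixels"]
        assert len(df) == 2
        assert df.EncodedPixels.iloc[1] == "-1"
        np.testing.assert_array_equal(decode_rle(df.EncodedPixels.iloc[0], 64, 64), mask)

    def test_duplicate_id_rejected(self, tmp_path):
        z = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="duplicate"):
            write_submission([("a", z), ("a", z)], tmp_path / "s.csv")


def test_full_pipeline_yields_valid_submission(tmp_path):
    """phantoms -> tta -> ensemble -> upscale -> thresholds -> RLE rows that
    decode within bounds."""
    corpus = generate_corpus(PhantomConfig(image_size=64, n_images=4, positive_fraction=0.5, seed=5))
    images = [np.repeat((r.image / 255.0)[:, :, None], 3, axis=2).astype(np.float32) for r in corpus]
    models = [build_bunet("tiny_unet", seed=s) for s in (0, 1)]
    masks = predict_masks(
        models, images,
        ThresholdConfig(0.5, 1024),
        EnsembleConfig([("m0", 0.6), ("m1", 0.4)]),
        native_size=256,
    )
    path = write_submission([(r.image_id, m) for r, m in zip(corpus, masks)], tmp_path / "sub.csv")
    recs = load_annotations(path, 256, 256)
    assert len(recs) == 4
    for rec in recs.values():
        decoded = rec.to_mask()
        assert decoded.shape == (256, 256)


def test_threshold_order_flag(rng):
    """Thresholding at native vs model resolution are both available and
    produce binary masks of native size."""
    model = build_bunet("tiny_unet", seed=0)
    image = rng.random((64, 64, 3)).astype(np.float32)
    for at_native in (True, False):
        (mask,) = predict_masks(
            [model], [image], ThresholdConfig(0.5), None,
            use_tta=False, native_size=128, threshold_at_native=at_native,
        )
        assert mask.shape == (128, 128)
        assert set(np.unique(mask)) <= {0, 1}


def test_probability_map_noise_degrades_iou():
    """Higher surrogate-map noise strictly lowers mean IoU at B-TH 0.5."""
    from pneumoseg.metrics import mean_iou

    corpus = generate_corpus(PhantomConfig(image_size=64, n_images=50, positive_fraction=1.0, seed=2))
    masks = [r.mask for r in corpus]
    low = generate_probability_maps(masks, blur_sd=1.0, noise_sd=0.05, seed=0)[0]
    high = generate_probability_maps(masks, blur_sd=1.0, noise_sd=0.3, seed=0)[0]
    iou_low = mean_iou([binarize(m, 0.5) for m in low], masks)
    iou_high = mean_iou([binarize(m, 0.5) for m in high], masks)
    assert iou_high < iou_low
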