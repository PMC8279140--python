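"""Losses, schedule, recipes, training loop determinism and SWA."""

import math

import numpy as np
import pytest

from pneumoseg.nn import Tensor
from pneumoseg.train import (
    RECIPES,
    TrainRecipe,
    bce_dice_loss,
    bce_loss,
    cosine_lr,
    dice_loss,
    refresh_bn_stats,
    swa_average,
    train,
)
from pneumoseg.unet import build_bunet


class TestBce:
    def test_perfect_prediction_near_zero(self):
        assert bce_loss(np.array([1 - 1e-7]), np.array([1.0])) < 1e-5

    def test_coin_flip_is_ln2(self):
        assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(math.log(2), rel=1e-5)
        assert bce_loss(np.array([0.5, 0.5]), np.array([0.0, 1.0])) == pytest.approx(
            math.log(2), rel=1e-5
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([]), np.array([]))


class TestDice:
    def test_perfect_binary_prediction(self):
        m = np.zeros((8, 8), dtype=np.float32)
        m[2:4, 2:4] = 1
        assert dice_loss(m, m) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_limit(self):
        n = 256 * 256
        assert dice_loss(np.full(n, 1.0 - 1e-6), np.zeros(n)) == pytest.approx(1.0, abs=1e-3)

    def test_half_confidence_on_full_truth(self):
        n = 100_000
        assert dice_loss(np.full(n, 0.5), np.ones(n)) == pytest.approx(1 / 3, abs=1e-4)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestBceDice:
    def test_sum_of_terms(self, rng):
        p = rng.uniform(0.05, 0.95, size=(16, 16))
        y = (rng.random((16, 16)) < 0.3).astype(np.float64)
        assert bce_dice_loss(p, y) == pytest.approx(
            bce_loss(p, y) + dice_loss(p, y), rel=1e-6
        )

    def test_monotone_in_prediction_error(self, rng):
        """Moving every probability away from its label never lowers the loss."""
        y = (rng.random(200) < 0.3).astype(np.float64)
        p = rng.uniform(0.2, 0.8, size=200)
        worse = np.where(y == 1, p - 0.05, p + 0.05)
        assert bce_dice_loss(worse, y) > bce_dice_loss(p, y)

    def test_gradient_matches_finite_difference(self, rng):
        p = Tensor(rng.uniform(0.2, 0.8, size=(1, 1, 3, 3)).astype(np.float32), requires_grad=True)
        y = (rng.random((1, 1, 3, 3)) < 0.5).astype(np.float32)
        loss = bce_dice_loss(p, y)
        loss.backward()
        eps = 1e-3
        for idx in range(9):
            flat = p.data.ravel()
            old = flat[idx]
            flat[idx] = old + eps
            up = bce_dice_loss(p.data.copy(), y)
            flat[idx] = old - eps
            down = bce_dice_loss(p.data.copy(), y)
            flat[idx] = old
            numeric = (up - down) / (2 * eps)
            assert p.grad.ravel()[idx] == pytest.approx(numeric, abs=5e-3)


class TestCosineSchedule:
    def test_endpoints_match_recipe_table(self):
        for name, (start, end) in {
            "exp1": (1e-3, 1e-5), "exp2": (1e-4, 1e-6), "exp4": (1e-4, 1e-6), "exp7": (1e-4, 1e-6)
        }.items():
            r = RECIPES[name]
            assert (r.lr_start, r.lr_end) == (start, end)
            assert cosine_lr(0, 100, r.lr_start, r.lr_end) == pytest.approx(start)
            assert cosine_lr(100, 100, r.lr_start, r.lr_end) == pytest.approx(end)

    def test_midpoint(self):
        assert cosine_lr(50, 100, 1e-3, 1e-5) == pytest.approx(5.05e-4)

    def test_invalid_steps(self):
        with pytest.raises(ValueError):
            cosine_lr(0, 0, 1e-3, 1e-5)
        with pytest.raises(ValueError):
            cosine_lr(5, 4, 1e-3, 1e-5)


def test_recipe_presets_match_published_table():
    """Optimizer / LR schedule / batch / epochs / SWA window per experiment."""
    expected = {
        "exp1": ("sgd_momentum", 1e-3, 1e-5, 10, 60, 5),
        "exp2": ("adam", 1e-4, 1e-6, 6, 80, 4),
        "exp4": ("adam", 1e-4, 1e-6, 6, 80, 3),
        "exp7": ("adam", 1e-4, 1e-6, 4, 80, 4),
    }
    for name, (opt, lr0, lr1, batch, epochs, swa) in expected.items():
        r = RECIPES[name]
        assert (r.optimizer, r.lr_start, r.lr_end, r.batch_size, r.epochs, r.swa_last_k) == (
            opt, lr0, lr1, batch, epochs, swa
        )
    assert RECIPES["exp1"].momentum == 0.9


def test_recipe_validation():
    with pytest.raises(ValueError):
        TrainRecipe("adam", 1e-5, 1e-3, 4, 10, 2)  # start < end
    with pytest.raises(ValueError):
        TrainRecipe("adam", 1e-3, 1e-5, 4, 10, 11)  # swa window > epochs


class TestSwaAverage:
    def test_identical_checkpoints_unchanged(self, rng):
        ck = {"a": rng.normal(size=(3, 3)).astype(np.float32)}
        out = swa_average([ck, {k: v.copy() for k, v in ck.items()}])
        np.testing.assert_allclose(out["a"], ck["a"], atol=1e-7)

    def test_opposite_checkpoints_cancel(self, rng):
        w = rng.normal(size=5).astype(np.float32)
        out = swa_average([{"w": w}, {"w": -w}])
        np.testing.assert_allclose(out["w"], 0.0, atol=1e-7)

    def test_mean_matches_summation_oracle(self, rng):
        cks = [
            {"a": rng.normal(size=(2, 2)).astype(np.float32), "b": rng.normal(size=3).astype(np.float32)}
            for _ in range(3)
        ]
        out = swa_average(cks)
        for key in ("a", "b"):
            manual = (cks[0][key] + cks[1][key] + cks[2][key]) / 3.0  # independent sum
            np.testing.assert_allclose(out[key], manual, atol=1e-6)

    def test_structural_mismatch(self, rng):
        with pytest.raises(ValueError):
            swa_average([{"a": np.ones(2)}, {"b": np.ones(2)}])
        with pytest.raises(ValueError):
            swa_average([{"a": np.ones(2)}, {"a": np.ones(3)}])


@pytest.fixture(scope="module")
def short_run(training_samples):
    net = build_bunet("tiny_unet", seed=0)
    recipe = TrainRecipe("adam", 5e-3, 5e-5, batch_size=4, epochs=4, swa_last_k=2)
    return train(net, training_samples, recipe, seed=0)


class TestTrainingLoop:
    def test_checkpoint_retention(self, short_run):
        assert len(short_run.checkpoints) == 2

    def test_log_columns_and_length(self, short_run):
        assert list(short_run.log.columns) == ["epoch", "lr", "train_loss", "train_iou"]
        assert len(short_run.log) == 4
        assert short_run.log.lr.iloc[0] == pytest.approx(5e-3)
        assert short_run.log.lr.iloc[-1] == pytest.approx(5e-5)

    def test_swa_state_loaded_into_model(self, short_run):
        mean = swa_average(short_run.checkpoints)
        state = short_run.model.state_dict()
        key = next(k for k in mean if k.endswith("head.0.weight"))
        np.testing.assert_allclose(state[key], mean[key], atol=1e-7)

    def test_deterministic_under_fixed_seed(self, training_samples):
        recipe = TrainRecipe("adam", 5e-3, 5e-5, batch_size=4, epochs=2, swa_last_k=1)
        logs = []
        for _ in range(2):
            net = build_bunet("tiny_unet", seed=0)
            logs.append(train(net, training_samples, recipe, seed=0).log)
        assert logs[0].train_loss.tolist() == logs[1].train_loss.tolist()

    def test_empty_dataset_rejected(self):
        net = build_bunet("tiny_unet", seed=0)
        with pytest.raises(ValueError):
            train(net, [], RECIPES["exp1"], seed=0)


def test_refresh_bn_updates_running_stats(training_samples):
    net = build_bunet("tiny_unet", seed=0)
    from pneumoseg.nn.layers import BatchNorm2d

    bns = [m for _, m in net.named_modules() if isinstance(m, BatchNorm2d)]
    before = [bn.running_mean.copy() for bn in bns]
    refresh_bn_stats(net, training_samples, batch_size=4)
    after = [bn.running_mean for bn in bns]
    assert any(not np.allclose(b, a) for b, a in zip(before, after))
    assert all(float(bn.num_batches[0]) == 2.0 for bn in bns)
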