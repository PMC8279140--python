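"""BCE-Dice loss, cosine annealing, training loop and weight averaging.

The loss is the sum of mean binary cross-entropy and soft Dice loss
(1 - (2*sum(p*y) + eps) / (sum(p) + sum(y) + eps), eps = 1 for stability
on empty masks; probabilities are clamped to [1e-7, 1 - 1e-7] before
logs).  The learning rate follows a single cosine cycle from ``lr_start``
to ``lr_end`` stepped per epoch.  "SWA" here is terminal checkpoint
averaging — the element-wise mean of the last k epoch weights — followed
by a batch-norm statistics refresh over the training data; the schedule is
monotone, so there are no cyclic snapshots to collect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import mean_iou
from .nn import SGD, Adam, Tensor, no_grad
from .nn import autograd as ag
from .nn.layers import BatchNorm2d
from .unet import BUNet

__all__ = [
    "TrainRecipe",
    "RECIPES",
    "bce_loss",
    "dice_loss",
    "bce_dice_loss",
    "cosine_lr",
    "train",
    "TrainResult",
    "swa_average",
    "refresh_bn_stats",
]

_EPS_P = 1e-7
_DICE_SMOOTH = 1.0


@dataclass
class TrainRecipe:
    """One row of the experiment table: optimizer and schedule settings."""

    optimizer: str  # "sgd_momentum" | "adam"
    lr_start: float
    lr_end: float
    batch_size: int
    epochs: int
    swa_last_k: int
    momentum: float = 0.9

    def __post_init__(self):
        if not self.lr_start > self.lr_end > 0:
            raise ValueError("require lr_start > lr_end > 0")
        if self.swa_last_k > self.epochs:
            raise ValueError("swa_last_k cannot exceed epochs")


# the published training configurations (EXP1/2/4/7 are the four ensembled
# models; EXP3/5/6 are the variants they superseded)
RECIPES: dict[str, TrainRecipe] = {
    "exp1": TrainRecipe("sgd_momentum", 1e-3, 1e-5, batch_size=10, epochs=60, swa_last_k=5),
    "exp2": TrainRecipe("adam", 1e-4, 1e-6, batch_size=6, epochs=80, swa_last_k=4),
    "exp3": TrainRecipe("adam", 1e-3, 1e-5, batch_size=4, epochs=100, swa_last_k=4),
    "exp4": TrainRecipe("adam", 1e-4, 1e-6, batch_size=6, epochs=80, swa_last_k=3),
    "exp5": TrainRecipe("adam", 1e-4, 1e-6, batch_size=4, epochs=100, swa_last_k=4),
    "exp6": TrainRecipe("adam", 1e-4, 1e-6, batch_size=4, epochs=45, swa_last_k=3),
    "exp7": TrainRecipe("adam", 1e-4, 1e-6, batch_size=4, epochs=80, swa_last_k=4),
}


def _loss_tensors(pred, truth) -> tuple[Tensor, np.ndarray]:
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=np.float32))
    y = truth.data if isinstance(truth, Tensor) else np.asarray(truth, dtype=np.float32)
    if p.data.shape != y.shape:
        raise ValueError(f"shape mismatch: pred {p.data.shape} vs truth {y.shape}")
    if p.data.size == 0:
        raise ValueError("empty loss input")
    return p, y


def _maybe_float(value: Tensor, pred) -> float | Tensor:
    return value if isinstance(pred, Tensor) else float(value.data)


def bce_loss(pred, truth):
    """Mean binary cross-entropy -[y log p + (1-y) log(1-p)]."""
    p, y = _loss_tensors(pred, truth)
    pc = ag.clip(p, _EPS_P, 1.0 - _EPS_P)
    term = ag.log(pc) * y + ag.log(1.0 - pc) * (1.0 - y)
    return _maybe_float(ag.tmean(term) * -1.0, pred)


def dice_loss(pred, truth, smooth: float = _DICE_SMOOTH):
    """Soft Dice loss 1 - (2 sum(p*y) + eps) / (sum(p) + sum(y) + eps)."""
    p, y = _loss_tensors(pred, truth)
    inter = ag.tsum(p * y)
    denom = ag.tsum(p) + float(y.sum())
    out = 1.0 - (inter * 2.0 + smooth) / (denom + smooth)
    return _maybe_float(out, pred)


def bce_dice_loss(pred, truth):
    """BCE + soft Dice, the training objective."""
    p, y = _loss_tensors(pred, truth)
    out = bce_loss(p, y) + dice_loss(p, y)
    return _maybe_float(out, pred)


def cosine_lr(step: int, total_steps: int, lr_start: float, lr_end: float) -> float:
    """Single-cycle cosine annealing: lr_start at step 0, lr_end at the end."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    return lr_end + 0.5 * (lr_start - lr_end) * (1.0 + math.cos(math.pi * step / total_steps))


@dataclass
class TrainResult:
    model: BUNet
    checkpoints: list[dict[str, np.ndarray]]  # state dicts of the last k epochs
    log: pd.DataFrame  # per-epoch loss / IoU
    swa_state: dict[str, np.ndarray] | None = None


def _stack_batch(samples) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([np.transpose(s.tensor, (2, 0, 1)) for s in samples])
    ys = np.stack([s.mask[None].astype(np.float32) for s in samples])
    return xs.astype(np.float32), ys


def train(
    model: BUNet,
    data,
    recipe: TrainRecipe,
    augmentation=None,
    seed: int = 0,
    val_data=None,
    apply_swa: bool = True,
) -> TrainResult:
    """Train a B-UNet on a sequence of ModelInput samples.

    ``augmentation`` is an optional ``(ModelInput, rng) -> ModelInput``
    callable applied per sample per epoch.  Checkpoints of the last
    ``recipe.swa_last_k`` epochs are retained; with ``apply_swa`` their
    average (after a BN statistics refresh) is loaded into the returned
    model.  Fully deterministic for a fixed seed.
    """
    data = list(data)
    if not data:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)
    params = model.parameters()
    if recipe.optimizer == "sgd_momentum":
        opt = SGD(params, recipe.lr_start, momentum=recipe.momentum)
    elif recipe.optimizer == "adam":
        opt = Adam(params, recipe.lr_start)
    else:
        raise ValueError(f"unknown optimizer {recipe.optimizer!r}")

    checkpoints: list[dict[str, np.ndarray]] = []
    rows = []
    for epoch in range(recipe.epochs):
        opt.lr = cosine_lr(epoch, max(recipe.epochs - 1, 1), recipe.lr_start, recipe.lr_end)
        order = rng.permutation(len(data))
        model.train()
        losses = []
        preds, truths = [], []
        for start in range(0, len(order), recipe.batch_size):
            batch = [data[i] for i in order[start : start + recipe.batch_size]]
            if augmentation is not None:
                batch = [augmentation(s, rng) for s in batch]
            x, y = _stack_batch(batch)
            out = model(Tensor(x))
            loss = bce_dice_loss(out, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {float(loss.data)} at epoch {epoch}, "
                    f"batch starting {start} (lr={opt.lr:.2e})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            preds.extend((out.data[:, 0] > 0.5).astype(np.uint8))
            truths.extend(y[:, 0].astype(np.uint8))
        row = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "train_iou": mean_iou(preds, truths),
        }
        if val_data:
            row.update(_validate(model, val_data, recipe.batch_size))
        rows.append(row)
        if epoch >= recipe.epochs - recipe.swa_last_k:
            checkpoints.append(model.state_dict())

    result = TrainResult(model=model, checkpoints=checkpoints, log=pd.DataFrame(rows))
    if apply_swa and checkpoints:
        result.swa_state = swa_average(checkpoints)
        model.load_state_dict(result.swa_state)
        refresh_bn_stats(model, data, recipe.batch_size)
    return result


def _validate(model, val_data, batch_size) -> dict[str, float]:
    model.eval()
    losses, preds, truths = [], [], []
    for start in range(0, len(val_data), batch_size):
        x, y = _stack_batch(val_data[start : start + batch_size])
        with no_grad():
            out = model(Tensor(x))
        losses.append(float(bce_dice_loss(out, y).data))
        preds.extend((out.data[:, 0] > 0.5).astype(np.uint8))
        truths.extend(y[:, 0].astype(np.uint8))
    return {"val_loss": float(np.mean(losses)), "val_iou": mean_iou(preds, truths)}


def swa_average(checkpoints: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Element-wise arithmetic mean of structurally identical weight sets."""
    if not checkpoints:
        raise ValueError("need at least one checkpoint")
    keys = set(checkpoints[0])
    for ck in checkpoints[1:]:
        if set(ck) != keys:
            raise ValueError("checkpoint structure mismatch")
        for k in keys:
            if ck[k].shape != checkpoints[0][k].shape:
                raise ValueError(f"checkpoint shape mismatch for {k}")
    return {
        k: np.mean([ck[k] for ck in checkpoints], axis=0, dtype=np.float64).astype(np.float32)
        for k in keys
    }


def refresh_bn_stats(model: BUNet, data, batch_size: int = 8) -> None:
    """Recompute BN running statistics after weight averaging.

    Averaged weights change every layer's activation distribution, so the
    stored running moments no longer match; one cumulative-average pass
    over the training inputs restores them.  No-op for BN-free models.
    """
    bns = [m for _, m in model.named_modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.reset_running_stats()
        bn.momentum = None  # cumulative average
    model.train()
    data = list(data)
    for start in range(0, len(data), batch_size):
        x, _ = _stack_batch(data[start : start + batch_size])
        with no_grad():
            model(Tensor(x))
    for bn, m in zip(bns, saved):
        bn.momentum = m
    model.eval()
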