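"""Training protocol: cross-entropy, Adam + step learning-rate decay,
augmentation on the training split only, k-fold cross-validation, and
best-on-validation checkpoint selection.

The validation selection metric is the mean Dice over foreground classes.
One master seed derives every RNG stream (fold assignment, augmentation,
weight init, batch shuffling) so a run is replayable end to end.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .dataio import AugmentationConfig, augment, make_folds
from .evaluation import confusion, compute_metrics
from .network import MultiScaleSegNet, NetworkConfig


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.002
    max_epochs: int = 300
    batch_size: int = 4
    steplr_step: int = 50
    steplr_gamma: float = 0.5
    seed: int = 0
    fold_count: int = 4
    crop: tuple | None = None            # (height, width) or None to keep size
    augmentation: AugmentationConfig | None = None

    def validate(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 < self.steplr_gamma <= 1:
            raise ValueError("steplr_gamma must lie in (0, 1]")
        if self.batch_size < 1 or self.steplr_step < 1:
            raise ValueError("batch_size and steplr_step must be >= 1")


@dataclass
class TrainState:
    """Bookkeeping for one training run."""

    epoch: int = 0
    best_val_metric: float = -np.inf
    best_state: dict | None = None
    history: list = field(default_factory=list)  # (epoch, lr, loss, val_dice)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history,
                            columns=["epoch", "lr", "train_loss", "val_dice"])


def cross_entropy_loss(logits, target) -> Tensor:
    """Mean per-pixel negative log-softmax of the true class (a scalar).

    Accepts a (C, H, W) or (N, C, H, W) tensor/array; targets are integer
    masks of matching spatial shape with labels < C.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    target = np.asarray(target)
    if logits.ndim == 3:
        logits = ad.reshape(logits, (1,) + logits.shape)
        target = target[None]
    return ad.softmax_cross_entropy(logits, target)


def step_lr(lr0: float, epoch: int, step: int, gamma: float) -> float:
    """lr0 * gamma ** floor(epoch / step) — the step decay schedule."""
    return lr0 * gamma ** (epoch // step)


def mean_foreground_dice(model: MultiScaleSegNet, samples) -> float:
    """Mean Dice over foreground classes, pooled over the given samples."""
    n_classes = model.config.n_classes
    total = None
    for s in samples:
        pred = model.predict(s.image)
        counts = confusion(pred, s.mask, n_classes)
        total = counts if total is None else total + counts
    report = compute_metrics(total)
    fg = report.dice[1:]
    fg = fg[~np.isnan(fg)]
    return float(fg.mean()) if fg.size else 0.0


def _stack_batch(samples, idx):
    images = np.stack([samples[i].image for i in idx])[:, None]
    masks = np.stack([samples[i].mask for i in idx])
    return images, masks


def train_fold(train_samples, val_samples,
               net_config: NetworkConfig = NetworkConfig(),
               train_config: TrainConfig = TrainConfig(),
               model: MultiScaleSegNet | None = None,
               log=None) -> tuple[MultiScaleSegNet, TrainState]:
    """Train one model on one split; return (model-at-best, state).

    The learning rate follows ``lr0 * gamma^(epoch // step)``; after every
    epoch the mean foreground Dice on the validation split is logged and the
    best parameter snapshot is retained.  The returned model carries the
    best-on-validation weights.
    """
    train_config.validate()
    if not len(train_samples) or not len(val_samples):
        raise ValueError("train and validation splits must be non-empty")
    if model is None:
        model = MultiScaleSegNet(replace(net_config, seed=train_config.seed))
    rng = np.random.default_rng(train_config.seed + 1)
    opt = nn.Adam(model.parameters(), lr=train_config.learning_rate)
    state = TrainState()

    if train_config.crop is not None:
        from .dataio import crop_or_pad
        train_samples = [crop_or_pad(s, train_config.crop) for s in train_samples]
        val_samples = [crop_or_pad(s, train_config.crop) for s in val_samples]

    n = len(train_samples)
    for epoch in range(train_config.max_epochs):
        lr = step_lr(train_config.learning_rate, epoch,
                     train_config.steplr_step, train_config.steplr_gamma)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            batch = [train_samples[i] for i in idx]
            if train_config.augmentation is not None:
                batch = [augment(s, train_config.augmentation,
                                 rng_seed=int(rng.integers(2 ** 31)))
                         for s in batch]
            images = np.stack([s.image for s in batch])[:, None]
            masks = np.stack([s.mask for s in batch])
            logits = model.forward(images)
            loss = ad.softmax_cross_entropy(logits, masks)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)!r}; "
                    "lower the learning rate or inspect the input range")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        val_dice = mean_foreground_dice(model, val_samples)
        state.epoch = epoch + 1
        state.history.append((epoch, lr, float(np.mean(losses)), val_dice))
        if val_dice > state.best_val_metric:
            state.best_val_metric = val_dice
            state.best_state = copy.deepcopy(model.state_dict())
        if log is not None:
            log(f"epoch {epoch:3d}  lr {lr:.6f}  "
                f"loss {np.mean(losses):.4f}  val_dice {val_dice:.4f}")

    if state.best_state is not None:
        model.load_state_dict(state.best_state)
    return model, state


def cross_validate(pool_samples, k: int = 4,
                   net_config: NetworkConfig = NetworkConfig(),
                   train_config: TrainConfig = TrainConfig(),
                   log=None):
    """k-fold cross-validation over a training pool.

    Returns (states, table): one :class:`TrainState` per fold and a
    per-class Dice table with across-fold mean and standard deviation in
    the usual "value +/- spread" style.
    """
    if len(pool_samples) < k:
        raise ValueError("pool smaller than the number of folds")
    ids = list(range(len(pool_samples)))
    folds = make_folds(ids, k, seed=train_config.seed)
    states = []
    per_fold_dice = []
    n_classes = net_config.n_classes
    from .dataio import NR206_CLASS_NAMES
    names = (NR206_CLASS_NAMES if n_classes == len(NR206_CLASS_NAMES)
             else tuple(f"class_{c}" for c in range(n_classes)))

    for fold in folds:
        train_s = [pool_samples[i] for i in fold.train]
        val_s = [pool_samples[i] for i in fold.val]
        model, state = train_fold(train_s, val_s, net_config,
                                  replace(train_config,
                                          seed=train_config.seed + fold.fold_index),
                                  log=log)
        states.append(state)
        total = None
        for s in val_s:
            counts = confusion(model.predict(s.image), s.mask, n_classes)
            total = counts if total is None else total + counts
        per_fold_dice.append(compute_metrics(total).dice)

    dice = np.asarray(per_fold_dice)  # (k, C)
    table = pd.DataFrame({
        "class": names,
        "dice_mean": np.nanmean(dice, axis=0),
        "dice_std": np.nanstd(dice, axis=0),
    })
    table["dice"] = [f"{m * 100:.1f} ± {s * 100:.1f}"
                     for m, s in zip(table["dice_mean"], table["dice_std"])]
    return states, table
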