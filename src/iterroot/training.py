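"""Training loop with on-the-fly augmentation and Dice-monitored stopping.

Defaults reproduce the best row of the original hyper-parameter search:
learning rate 0.00332 with multiplicative decay 0.89661 per epoch,
cross-entropy weight alpha = 0.42715 with Dice weight beta = 1.0,
early stopping with patience 17, tolerance 0.010 over a 7-epoch window,
a maximum of 200 epochs and batch size 32.  Optimization uses adaptive
moment estimation (Adam); the optimized objective is the final
sub-network's combined loss (``supervision_mode="last"``) or the sum
over all heads (``"sum"``, deep supervision).
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .loss_metrics import LossWeights, combined_loss, score_pair
from .network import IterRoot, save_checkpoint
from .nn import Adam, Tensor


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.00332
    lr_decay: float = 0.89661
    alpha: float = 0.42715
    beta: float = 1.0
    stopping_patience: int = 17
    stopping_tolerance: float = 0.010
    stopping_epochs: int = 7
    max_epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    augment: bool = True
    supervision_mode: str = "last"        # or "sum" (deep supervision)
    plateau_rule: str = "window"          # or "best": best-so-far plateau

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.stopping_patience < 1 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("patience, max_epochs and batch_size must be positive")
        if self.stopping_tolerance <= 0:
            raise ValueError("stopping_tolerance must be positive")
        if self.stopping_epochs < 0:
            raise ValueError("stopping_epochs must be nonnegative")
        if self.stopping_epochs > self.stopping_patience:
            raise ValueError("stopping_epochs cannot exceed stopping_patience")
        if self.supervision_mode not in ("last", "sum"):
            raise ValueError("supervision_mode must be 'last' or 'sum'")
        if self.plateau_rule not in ("window", "best"):
            raise ValueError("plateau_rule must be 'window' or 'best'")

    def loss_weights(self) -> LossWeights:
        return LossWeights(alpha=self.alpha, beta=self.beta)


@dataclass
class EarlyStopState:
    epoch: int = 0
    monitored_dice_history: list[float] = field(default_factory=list)
    stopped: bool = False
    stop_epoch: int | None = None

    def record(self, dice: float) -> None:
        self.epoch += 1
        self.monitored_dice_history.append(float(dice))


@dataclass
class TrainReport:
    train_loss: list[float]
    monitor_loss: list[float]
    monitor_dice: list[float]
    final_epoch: int
    best_epoch: int
    best_monitor_dice: float
    checkpoint_path: str | None
    config: dict
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ----------------------------------------------------------------------
# augmentation
# ----------------------------------------------------------------------

def augment_pair(image: np.ndarray, mask: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random rotation up to 90 degrees plus independent flips.

    The identical geometric transform is applied to both arrays: bilinear
    interpolation for the image, nearest-neighbour for the mask, with
    reflection fill, so the mask stays binary and registered.
    """
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask dimensions differ")
    angle = float(rng.uniform(0.0, 90.0))
    flip_h = bool(rng.random() < 0.5)
    flip_v = bool(rng.random() < 0.5)
    img, msk = image, mask
    if angle > 0.0:
        img = ndimage.rotate(img, angle, axes=(1, 0), reshape=False,
                             order=1, mode="reflect")
        msk = ndimage.rotate(msk, angle, axes=(1, 0), reshape=False,
                             order=0, mode="reflect")
    if flip_h:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if flip_v:
        img = img[::-1]
        msk = msk[::-1]
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Multiplicative decay: learning_rate * lr_decay ** epoch."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return config.learning_rate * config.lr_decay ** epoch


def early_stop_decision(state: EarlyStopState, config: TrainConfig) -> bool:
    """Stop when monitored Dice has improved by <= tolerance over the window.

    Never stops before ``stopping_patience`` epochs.  The improvement is
    current Dice minus the value ``stopping_epochs`` epochs earlier
    (``plateau_rule="window"``) or minus the best value seen before the
    window (``"best"``); a window longer than the history is treated as
    not yet evaluable.
    """
    hist = state.monitored_dice_history
    if not hist:
        raise ValueError("monitored Dice history is empty")
    if state.epoch < config.stopping_patience:
        return False
    w = config.stopping_epochs
    if w >= len(hist):
        return False
    if config.plateau_rule == "window":
        reference = hist[-1 - w]
    else:
        reference = max(hist[:-w]) if w > 0 else max(hist[:-1], default=hist[-1])
    return (hist[-1] - reference) <= config.stopping_tolerance


# ----------------------------------------------------------------------
# the loop
# ----------------------------------------------------------------------

def _as_batch_tensor(images: np.ndarray) -> Tensor:
    return Tensor(np.asarray(images, dtype=np.float32).transpose(0, 3, 1, 2))


def _monitor(model: IterRoot, images: np.ndarray, masks: np.ndarray,
             weights: LossWeights, threshold: float,
             batch_size: int) -> tuple[float, float]:
    """(mean combined loss, mean per-patch Dice) of the final head."""
    model.eval()
    losses, dices = [], []
    with nn.no_grad():
        for i in range(0, len(images), batch_size):
            xb = _as_batch_tensor(images[i:i + batch_size])
            yb = masks[i:i + batch_size].astype(np.float32)
            yhat = model(xb)[-1]
            y_t = Tensor(yb[:, None])
            losses.append(float(combined_loss(y_t, yhat, weights).data))
            pred = (yhat.data[:, 0] >= threshold).astype(np.uint8)
            for j in range(pred.shape[0]):
                dices.append(score_pair(pred[j], yb[j].astype(np.uint8)).dsc)
    model.train()
    return float(np.mean(losses)), float(np.mean(dices))


def train(model: IterRoot, train_images: np.ndarray, train_masks: np.ndarray,
          monitor_images: np.ndarray, monitor_masks: np.ndarray,
          config: TrainConfig = TrainConfig(),
          checkpoint_path=None,
          log=None) -> TrainReport:
    """Train a model on patch arrays; returns the per-epoch report.

    ``train_images``/``monitor_images`` are (n, H, W, 3) floats in [0, 1];
    masks are (n, H, W) binary.  The monitored quantity for early
    stopping is the monitor-set mean Dice of the final head binarized at
    the model's configured threshold; the best-monitor-Dice weights are
    restored into ``model`` and written to ``checkpoint_path`` (if given)
    at the end.
    """
    if len(train_images) == 0 or len(monitor_images) == 0:
        raise ValueError("training and monitor sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    weights = config.loss_weights()
    threshold = model.config.binarize_threshold
    opt = Adam(model.parameters(), lr=config.learning_rate)
    state = EarlyStopState()
    train_hist: list[float] = []
    mon_loss_hist: list[float] = []
    best_dice, best_epoch, best_state = -1.0, -1, None

    n = len(train_images)
    for epoch in range(config.max_epochs):
        opt.lr = lr_at_epoch(config, epoch)
        order = rng.permutation(n)
        model.train()
        epoch_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            imgs = train_images[idx]
            msks = train_masks[idx]
            if config.augment:
                pairs = [augment_pair(im, mk, rng) for im, mk in zip(imgs, msks)]
                imgs = np.stack([p[0] for p in pairs])
                msks = np.stack([p[1] for p in pairs])
            xb = _as_batch_tensor(imgs)
            y_t = Tensor(msks.astype(np.float32)[:, None])
            maps = model(xb)
            if config.supervision_mode == "sum":
                loss = combined_loss(y_t, maps[0], weights)
                for m in maps[1:]:
                    loss = loss + combined_loss(y_t, m, weights)
            else:
                loss = combined_loss(y_t, maps[-1], weights)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss = {value}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        train_hist.append(float(np.mean(epoch_losses)))
        mon_loss, mon_dice = _monitor(model, monitor_images, monitor_masks,
                                      weights, threshold, config.batch_size)
        mon_loss_hist.append(mon_loss)
        state.record(mon_dice)
        if mon_dice > best_dice:
            best_dice, best_epoch = mon_dice, epoch
            best_state = copy.deepcopy(model.state_arrays())
        if log is not None:
            log(f"epoch {epoch:3d}  lr {opt.lr:.6f}  train {train_hist[-1]:.4f}  "
                f"monitor {mon_loss:.4f}  dice {mon_dice:.4f}")
        if early_stop_decision(state, config):
            state.stopped = True
            state.stop_epoch = state.epoch
            break

    if best_state is not None:
        model.load_state_arrays(best_state)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path,
                        extra={"train_config": asdict(config),
                               "best_epoch": best_epoch,
                               "best_monitor_dice": best_dice})
    return TrainReport(
        train_loss=train_hist,
        monitor_loss=mon_loss_hist,
        monitor_dice=state.monitored_dice_history,
        final_epoch=state.epoch,
        best_epoch=best_epoch,
        best_monitor_dice=best_dice,
        checkpoint_path=str(checkpoint_path) if checkpoint_path else None,
        config=asdict(config),
        seed=config.seed,
    )
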