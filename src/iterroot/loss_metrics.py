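"""Training loss and segmentation quality metrics.

The training objective combines a weighted binary cross-entropy term,
which drives per-pixel classification, with a Dice term, which measures
overall overlap and is robust to the strong foreground/background class
imbalance of thin-root imagery:

    loss = alpha * H(y, yhat) + beta * (1 - D(y, yhat))

where H is binary cross-entropy, D is the soft Dice similarity
(2*sum(y*yhat) / (sum(y) + sum(yhat))), y the binary ground truth and
yhat the predicted probability map.  Quality metrics (DSC, IoU,
sensitivity, specificity, accuracy) are computed from per-pixel confusion
counts between two binary masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class LossWeights:
    """Weights of the two loss terms.

    ``alpha`` scales the cross-entropy term, ``beta`` the Dice term
    (fixed to 1.0 during the original hyper-parameter search so the
    objective always rewards Dice improvement).  ``epsilon`` guards the
    logarithm and the Dice denominator.
    """

    alpha: float = 0.42715
    beta: float = 1.0
    epsilon: float = 1e-7
    bce_reduction: str = "mean"          # "mean" | "sum"
    dice_as_similarity: bool = False     # True: add +beta*D (printed form)

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")
        if not (0 < self.epsilon < 1e-3):
            raise ValueError("epsilon must lie in (0, 1e-3)")
        if self.bce_reduction not in ("mean", "sum"):
            raise ValueError("bce_reduction must be 'mean' or 'sum'")


def _pair(y, yhat):
    y_t = y if isinstance(y, Tensor) else Tensor(y)
    yhat_t = yhat if isinstance(yhat, Tensor) else Tensor(yhat)
    if y_t.shape != yhat_t.shape:
        raise ValueError(f"shape mismatch: y {y_t.shape} vs yhat {yhat_t.shape}")
    return y_t, yhat_t


def bce(y, yhat, reduction: str = "mean", epsilon: float = 1e-7) -> Tensor:
    """Binary cross-entropy -sum(y log yhat + (1-y) log(1-yhat)).

    ``yhat`` is clamped to [epsilon, 1-epsilon] before the logarithm.
    ``reduction`` "sum" gives the literal pixel sum; "mean" divides by N
    so the term stays on a comparable scale to the Dice term.
    """
    y_t, yhat_t = _pair(y, yhat)
    p = nn.clip(yhat_t, epsilon, 1.0 - epsilon)
    ll = y_t * nn.log(p) + (1.0 - y_t) * nn.log(1.0 - p)
    total = -ll.sum()
    if reduction == "mean":
        return total * (1.0 / y_t.data.size)
    return total


def soft_dice(y, yhat, epsilon: float = 1e-7) -> Tensor:
    """Soft Dice similarity (2*sum(y*yhat)+eps) / (sum(y)+sum(yhat)+eps).

    Equals the hard Dice coefficient when ``yhat`` is binary; the eps
    smoothing makes two empty masks score 1.0.
    """
    y_t, yhat_t = _pair(y, yhat)
    inter = (y_t * yhat_t).sum()
    denom = y_t.sum() + yhat_t.sum()
    return (2.0 * inter + epsilon) / (denom + epsilon)


def combined_loss(y, yhat, weights: LossWeights = LossWeights()) -> Tensor:
    """alpha * BCE + beta * (1 - soft Dice) (minimization increases Dice)."""
    h = bce(y, yhat, reduction=weights.bce_reduction, epsilon=weights.epsilon)
    d = soft_dice(y, yhat, epsilon=weights.epsilon)
    dice_term = d if weights.dice_as_similarity else (1.0 - d)
    return weights.alpha * h + weights.beta * dice_term


# ----------------------------------------------------------------------
# hard-mask metrics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class SegmentationScores:
    dsc: float
    iou: float
    sensitivity: float
    specificity: float
    accuracy: float
    flags: tuple[str, ...] = field(default=())


def confusion(pred, truth) -> ConfusionCounts:
    """Per-pixel confusion tally between two binary masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: int, den: int) -> float:
    # vacuous denominator (nothing of that kind to find) counts as success
    return 1.0 if den == 0 else num / den


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN)."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def iou(c: ConfusionCounts) -> float:
    """Intersection over union TP / (TP + FP + FN)."""
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate TN / (TN + FP)."""
    return _ratio(c.tn, c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / N; inflated by class imbalance, reported for completeness."""
    return _ratio(c.tp + c.tn, c.total)


def score_pair(pred, truth) -> SegmentationScores:
    """All five metrics for one predicted/ground-truth mask pair.

    Vacuous cases (no true foreground, no true background, ...) score 1.0
    and are flagged so dataset means remain auditable.
    """
    c = confusion(pred, truth)
    flags = []
    if c.tp + c.fn == 0:
        flags.append("no_true_foreground")
    if c.tn + c.fp == 0:
        flags.append("no_true_background")
    if 2 * c.tp + c.fp + c.fn == 0:
        flags.append("both_masks_empty")
    return SegmentationScores(
        dsc=dsc(c), iou=iou(c), sensitivity=sensitivity(c),
        specificity=specificity(c), accuracy=accuracy(c),
        flags=tuple(flags),
    )
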