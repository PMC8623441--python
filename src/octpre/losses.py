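"""Combined weighted multi-class logistic + Dice training loss.

The total loss is

    L = alpha * L_log + beta * (1 - sum_c lambda_c * Dice_c)

where L_log is a per-class-normalised, pixel-weighted categorical
cross-entropy and Dice_c a soft (probability-valued) Dice score.  Pixel
weights boost class-boundary pixels (q1) and the two thin classes of
interest, preretinal space and retina (q2); class weights lambda_c are
inverse-pixel-count normalised to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-7
N_CLASSES = 4
CLASSES_OF_INTEREST = (1, 2)  # preretinal space, retina

__all__ = [
    "EPS",
    "LossConfig",
    "one_hot",
    "class_weights",
    "pixel_weight_map",
    "log_loss",
    "soft_dice_per_class",
    "dice_loss",
    "total_loss",
    "total_loss_grad",
]


@dataclass
class LossConfig:
    """Weights of the combined loss.

    alpha/beta weight the logistic and Dice components; q1 is the extra
    weight on boundary pixels, q2 the extra weight on classes 1 and 2;
    lambda_c are the four class weights (must sum to 1).
    """

    alpha: float = 1.0
    beta: float = 0.5
    q1: float = 10.0
    q2: float = 5.0
    lambda_c: np.ndarray = field(
        default_factory=lambda: np.full(N_CLASSES, 1.0 / N_CLASSES)
    )

    def __post_init__(self):
        self.lambda_c = np.asarray(self.lambda_c, dtype=np.float64)
        if min(self.alpha, self.beta, self.q1, self.q2) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda_c.shape != (N_CLASSES,):
            raise ValueError("lambda_c must have 4 entries")
        if abs(self.lambda_c.sum() - 1.0) > 1e-9:
            raise ValueError("lambda_c must sum to 1")


def one_hot(mask: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(H, W) integer mask -> (C, H, W) binary one-hot encoding."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= n_classes:
        raise ValueError("mask labels out of range")
    return (np.arange(n_classes)[:, None, None] == mask[None]).astype(np.float64)


def class_weights(pixel_counts) -> np.ndarray:
    """Inverse-count class weights: lambda_c = (1/n_c) / sum_c' (1/n_c')."""
    n = np.asarray(pixel_counts, dtype=np.float64)
    if np.any(n <= 0):
        raise ValueError("all class pixel counts must be positive "
                         "(merge or exclude absent classes)")
    inv = 1.0 / n
    return inv / inv.sum()


def pixel_weight_map(gt_onehot: np.ndarray, q1: float = 10.0,
                     q2: float = 5.0) -> np.ndarray:
    """Per-class pixel weights w_c = 1 + q1*[vertical edge] + q2*[c in {1,2}].

    The edge indicator is a one-pixel vertical difference of each binary
    class mask: a pixel is an edge pixel when its value differs from the
    pixel directly above it.
    """
    gt = np.asarray(gt_onehot, dtype=np.float64)
    edges = np.zeros_like(gt)
    edges[:, 1:, :] = np.abs(np.diff(gt, axis=1)) > 0
    w = 1.0 + q1 * edges
    for c in CLASSES_OF_INTEREST:
        w[c] += q2
    return w


def _counts(gt_onehot):
    return gt_onehot.sum(axis=(1, 2))


def log_loss(gt_onehot: np.ndarray, probs: np.ndarray,
             weights: np.ndarray | None = None) -> float:
    """Weighted categorical cross-entropy, normalised per class pixel count.

    Classes absent from the ground truth contribute 0.
    """
    gt = np.asarray(gt_onehot, dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    if weights is None:
        weights = np.ones_like(gt)
    nc = _counts(gt)
    total = 0.0
    for c in range(gt.shape[0]):
        if nc[c] == 0:
            continue
        total -= (weights[c] * gt[c] * np.log(p[c] + EPS)).sum() / nc[c]
    return float(total)


def soft_dice_per_class(gt_onehot: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Soft Dice_c = (2 * sum(I_c * Ihat_c) + eps) / (sum I_c + sum Ihat_c + eps).

    The epsilon makes an absent class with near-zero predicted mass score 1.
    """
    gt = np.asarray(gt_onehot, dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    inter = (gt * p).sum(axis=(1, 2))
    denom = gt.sum(axis=(1, 2)) + p.sum(axis=(1, 2))
    return (2.0 * inter + EPS) / (denom + EPS)


def dice_loss(gt_onehot, probs, lambda_c) -> float:
    return float(1.0 - (np.asarray(lambda_c) * soft_dice_per_class(gt_onehot, probs)).sum())


def total_loss(gt_onehot: np.ndarray, probs: np.ndarray,
               cfg: LossConfig, weights: np.ndarray | None = None) -> float:
    """L = alpha * L_log + beta * L_Dice (weights default to the q1/q2 map)."""
    if weights is None:
        weights = pixel_weight_map(gt_onehot, cfg.q1, cfg.q2)
    return (cfg.alpha * log_loss(gt_onehot, probs, weights)
            + cfg.beta * dice_loss(gt_onehot, probs, cfg.lambda_c))


def total_loss_grad(gt_onehot: np.ndarray, probs: np.ndarray,
                    cfg: LossConfig, weights: np.ndarray | None = None) -> np.ndarray:
    """Analytic dL/dprobs of :func:`total_loss` (same shape as ``probs``)."""
    gt = np.asarray(gt_onehot, dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    if weights is None:
        weights = pixel_weight_map(gt, cfg.q1, cfg.q2)
    grad = np.zeros_like(p)
    nc = _counts(gt)
    # log-loss term
    for c in range(gt.shape[0]):
        if nc[c] == 0:
            continue
        grad[c] -= cfg.alpha * weights[c] * gt[c] / (p[c] + EPS) / nc[c]
    # Dice term: d/dp of (2S+eps)/D with S = sum(I*p), D = sum I + sum p + eps
    inter = (gt * p).sum(axis=(1, 2))
    denom = gt.sum(axis=(1, 2)) + p.sum(axis=(1, 2)) + EPS
    for c in range(gt.shape[0]):
        ddice = (2.0 * gt[c] * denom[c] - (2.0 * inter[c] + EPS)) / denom[c] ** 2
        grad[c] -= cfg.beta * cfg.lambda_c[c] * ddice
    return grad
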