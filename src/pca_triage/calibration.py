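"""Calibrated segmentation loss and the polynomial learning-rate schedule.

Stand-alone numpy reference implementations, unit-testable on tiny arrays
(no training loop here). The calibrated loss augments the usual equal-weight
average of soft-Dice and cross-entropy with two calibration devices:

* label smoothing — one-hot targets are mixed towards the uniform
  distribution, y' = y(1-α) + α/K, defaults α = 0.2;
* a margin penalty — a hinge on pairwise logit gaps, penalising any gap of
  the per-voxel maximum logit over another class logit that exceeds the
  margin m (default 10), which discourages over-confident logits.

With α = 0 and m → ∞ the loss reduces exactly to the plain average of
soft-Dice and cross-entropy.

Array layout: logits/targets are (K, *spatial) with classes first; class 0
is background for the Dice term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibratedLossConfig",
    "smooth_labels",
    "margin_penalty",
    "soft_dice_loss",
    "cross_entropy",
    "calibrated_loss",
    "poly_lr",
]

_DICE_EPS = 1e-5


@dataclass
class CalibratedLossConfig:
    """Smoothing factor, margin and term weights of the calibrated loss."""

    alpha: float = 0.2
    margin: float = 10.0
    n_classes: int = 2
    dice_weight: float = 0.5
    ce_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def smooth_labels(onehot: np.ndarray, alpha: float, n_classes: int | None = None) -> np.ndarray:
    """Label smoothing: y' = y(1-α) + α/K, rows remain distributions."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    onehot = np.asarray(onehot, dtype=float)
    k = n_classes if n_classes is not None else onehot.shape[0]
    return onehot * (1.0 - alpha) + alpha / k


def margin_penalty(logits: np.ndarray, margin: float) -> float:
    """Hinge on per-voxel logit gaps: mean over voxels and classes of
    max(0, (max-logit − logit_k) − m). Zero when every gap is within m."""
    logits = np.asarray(logits, dtype=float)
    gaps = logits.max(axis=0, keepdims=True) - logits
    return float(np.maximum(gaps - margin, 0.0).mean())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def soft_dice_loss(probs: np.ndarray, targets: np.ndarray, eps: float = _DICE_EPS) -> float:
    """1 − soft Dice over foreground channels (class 0 is background)."""
    p = probs[1:]
    g = targets[1:]
    num = 2.0 * float((p * g).sum()) + eps
    den = float(p.sum()) + float(g.sum()) + eps
    return 1.0 - num / den


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean per-voxel cross-entropy of softmax(logits) against target rows."""
    logz = logits - logits.max(axis=0, keepdims=True)
    log_probs = logz - np.log(np.exp(logz).sum(axis=0, keepdims=True))
    return float(-(targets * log_probs).sum(axis=0).mean())


def calibrated_loss(
    logits: np.ndarray, onehot_targets: np.ndarray, cfg: CalibratedLossConfig | None = None
) -> float:
    """Weighted soft-Dice + cross-entropy on smoothed labels + margin penalty.

    Defaults: equal Dice/CE weights, α = 0.2, margin = 10. The Dice term uses
    hard (unsmoothed) targets; smoothing applies to the cross-entropy target
    distribution.
    """
    cfg = cfg or CalibratedLossConfig()
    logits = np.asarray(logits, dtype=float)
    targets = np.asarray(onehot_targets, dtype=float)
    if logits.shape != targets.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {targets.shape}")
    probs = _softmax(logits)
    smoothed = smooth_labels(targets, cfg.alpha, cfg.n_classes)
    loss = cfg.dice_weight * soft_dice_loss(probs, targets) + cfg.ce_weight * cross_entropy(
        logits, smoothed
    )
    if math.isfinite(cfg.margin):
        loss += margin_penalty(logits, cfg.margin)
    return float(loss)


def poly_lr(epoch: int, epoch_max: int, base_lr: float = 1e-3, power: float = 0.9) -> float:
    """Polynomial decay: base_lr · (1 − epoch/epoch_max)^power."""
    if epoch_max <= 0:
        raise ValueError("epoch_max must be positive")
    if not 0 <= epoch <= epoch_max:
        raise ValueError("epoch must lie in [0, epoch_max]")
    return float(base_lr * (1.0 - epoch / epoch_max) ** power)
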