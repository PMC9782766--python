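"""Dice-based losses for binary volumetric segmentation.

The training objective is the soft Dice loss of Milletari et al.,

    L_Dice(P, T) = 1 - (2 * sum(P*T) + eps) / (sum(P) + sum(T) + eps),

computed on the continuous network output ``P`` in [0, 1] against the binary
ground truth ``T``. For a lesion-free image (``sum(T) = 0``) this loss sits
near 1 regardless of ``P`` — it equals ``1 - eps / (sum(P) + eps)`` — so its
gradient is tiny and normal brains contribute almost nothing to training.

The balanced Dice loss (BDL) fixes that by re-weighting lesion-free images:
with ``alpha = max(T)`` per image,

    L_BD = L_Dice            if alpha = 1  (lesion present)
    L_BD = beta * L_Dice     if alpha = 0  (lesion-free)

so the weight ``beta`` (default 100, selected by five-fold cross-validation)
amplifies both the value and the gradient of the loss on empty-mask images.
Batch losses are summed, not averaged, over images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "dsc",
    "soft_dice_loss",
    "soft_dice_loss_grad",
    "balanced_dice_loss",
    "balanced_dice_loss_grad",
    "batch_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters of the Dice-based losses.

    Parameters
    ----------
    epsilon : float
        Smoothing constant added to numerator and denominator of the soft
        Dice ratio. Keeps the loss defined (and exactly 0) when both the
        prediction and the truth are empty. Must be positive.
    beta : float
        Weight multiplied onto the per-image loss when the ground-truth mask
        is all-zero (lesion-free brain). ``beta = 1`` recovers the plain soft
        Dice loss. Must be non-negative.
    """

    epsilon: float = 1e-5
    beta: float = 100.0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


def _check_aligned(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(
            f"prediction and truth shapes differ: {p.shape} vs {t.shape}"
        )
    return p, t


def dsc(p: np.ndarray, t: np.ndarray) -> float:
    """Sørensen–Dice coefficient ``2*sum(P*T) / (sum(P) + sum(T))``.

    ``p`` may be a probability map or a binary mask. When both inputs are
    empty (``sum(P) = sum(T) = 0``) the ratio is 0/0 and the convention here
    is 1.0: perfect agreement on emptiness.
    """
    p, t = _check_aligned(p, t)
    denom = p.sum() + t.sum()
    if denom == 0.0:
        return 1.0
    return float(2.0 * (p * t).sum() / denom)


def soft_dice_loss(
    p: np.ndarray, t: np.ndarray, cfg: LossConfig = LossConfig()
) -> float:
    """Epsilon-smoothed soft Dice loss, ``1 - (2*sum(PT)+eps)/(sum(P)+sum(T)+eps)``."""
    p, t = _check_aligned(p, t)
    num = 2.0 * (p * t).sum() + cfg.epsilon
    den = p.sum() + t.sum() + cfg.epsilon
    return float(1.0 - num / den)


def soft_dice_loss_grad(
    p: np.ndarray, t: np.ndarray, cfg: LossConfig = LossConfig()
) -> np.ndarray:
    """Analytic gradient of :func:`soft_dice_loss` with respect to ``p``.

    With ``num = 2*sum(PT) + eps`` and ``den = sum(P) + sum(T) + eps``:
    ``dL/dp_i = -(2*t_i*den - num) / den**2``.
    """
    p, t = _check_aligned(p, t)
    num = 2.0 * (p * t).sum() + cfg.epsilon
    den = p.sum() + t.sum() + cfg.epsilon
    return -(2.0 * t * den - num) / den**2


def balanced_dice_loss(
    p: np.ndarray, t: np.ndarray, cfg: LossConfig = LossConfig()
) -> float:
    """Balanced Dice loss: soft Dice loss, scaled by ``beta`` on empty masks.

    ``alpha = max(T)`` selects the branch: lesion images (``alpha = 1``) get
    the plain soft Dice loss; lesion-free images (``alpha = 0``) get
    ``beta`` times it, making them informative during training.
    """
    p, t = _check_aligned(p, t)
    base = soft_dice_loss(p, t, cfg)
    alpha = float(t.max()) if t.size else 0.0
    return base if alpha == 1.0 else float(cfg.beta) * base


def balanced_dice_loss_grad(
    p: np.ndarray, t: np.ndarray, cfg: LossConfig = LossConfig()
) -> np.ndarray:
    """Analytic gradient of :func:`balanced_dice_loss` with respect to ``p``."""
    p, t = _check_aligned(p, t)
    g = soft_dice_loss_grad(p, t, cfg)
    alpha = float(t.max()) if t.size else 0.0
    return g if alpha == 1.0 else float(cfg.beta) * g


def batch_loss(
    cases: list[tuple[np.ndarray, np.ndarray]],
    cfg: LossConfig = LossConfig(),
    use_bdl: bool = False,
) -> float:
    """Sum of per-image losses over a batch (the batch loss is a sum, not a mean)."""
    if not cases:
        raise ValueError("batch_loss requires a nonempty list of (P, T) cases")
    fn = balanced_dice_loss if use_bdl else soft_dice_loss
    return float(sum(fn(p, t, cfg) for p, t in cases))
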