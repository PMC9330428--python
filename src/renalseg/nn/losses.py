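"""Softmax, cross-entropy and soft-Dice losses with analytic gradients.

The training loss is the equally weighted sum of voxel-mean
cross-entropy and soft-Dice loss (smoothing constant 1, averaged over
classes).
"""

from __future__ import annotations

import numpy as np

DICE_SMOOTH = 1.0


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, ...) int labels -> (N, C, ...) float32 one-hot."""
    eye = np.eye(n_classes, dtype=np.float32)
    return np.moveaxis(eye[target], -1, 1)


def cross_entropy_loss(probs: np.ndarray, target: np.ndarray, eps: float = 1e-12) -> float:
    """Voxel-mean negative log-likelihood; probs (N, C, ...), target (N, ...)."""
    _check(probs, target)
    picked = np.take_along_axis(probs, target[:, None], axis=1)[:, 0]
    return float(-np.log(np.clip(picked, eps, None)).mean())


def soft_dice_loss(probs: np.ndarray, target: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    """1 - mean over classes of (2 sum(p*t) + s) / (sum(p) + sum(t) + s)."""
    _check(probs, target)
    n_classes = probs.shape[1]
    t = one_hot(target, n_classes)
    axes = (0,) + tuple(range(2, probs.ndim))
    inter = (probs * t).sum(axis=axes)
    a = 2.0 * inter + smooth
    b = probs.sum(axis=axes) + t.sum(axis=axes) + smooth
    return float(1.0 - (a / b).mean())


def combined_loss(probs: np.ndarray, target: np.ndarray) -> float:
    """Dice + cross-entropy, equal weights, on normalized probabilities."""
    return cross_entropy_loss(probs, target) + soft_dice_loss(probs, target)


def combined_loss_and_grad(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the logits."""
    _check(logits, target)
    n_classes = logits.shape[1]
    p = softmax(logits, axis=1)
    t = one_hot(target, n_classes)
    n_vox = target.size
    axes = (0,) + tuple(range(2, logits.ndim))

    picked = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    ce = float(-np.log(np.clip(picked, 1e-12, None)).mean())

    inter = (p * t).sum(axis=axes)
    a = 2.0 * inter + DICE_SMOOTH
    b = p.sum(axis=axes) + t.sum(axis=axes) + DICE_SMOOTH
    dice = float(1.0 - (a / b).mean())

    # d(ce)/dz is the classic softmax-CE shortcut; for the dice term we
    # differentiate w.r.t. p and push back through the softmax jacobian.
    g_ce = (p - t) / n_vox
    shape = (1, n_classes) + (1,) * (logits.ndim - 2)
    g_p = -(2.0 * t * b.reshape(shape) - a.reshape(shape)) / (b.reshape(shape) ** 2) / n_classes
    g_dice = p * (g_p - (g_p * p).sum(axis=1, keepdims=True))

    return ce + dice, (g_ce + g_dice).astype(np.float32)


def _check(pred: np.ndarray, target: np.ndarray) -> None:
    if pred.shape[0] != target.shape[0] or pred.shape[2:] != target.shape[1:]:
        raise ValueError(
            f"prediction shape {pred.shape} incompatible with target shape {target.shape}"
        )
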