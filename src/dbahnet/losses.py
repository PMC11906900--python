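"""Training objective: weighted sum of soft Dice loss and cross-entropy.

The Dice term is computed per foreground class on softmax probabilities with
a smoothing constant eps = 1e-5 in numerator and denominator, then averaged
over classes.  The cross-entropy term is the multi-class mean over voxels of
``-log p`` at the true class.  The combined loss is
``alpha * Dice + beta * CE`` with ``alpha = beta = 0.5`` by default.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, softmax

DICE_EPS = 1e-5
_LOG_CLAMP = 1e-12


def softmax_probs(logits: Tensor, class_axis: int = 1) -> Tensor:
    """Channel-wise softmax of network logits -> per-voxel probabilities."""
    nd = logits.ndim
    perm = [a for a in range(nd) if a != class_axis] + [class_axis]
    p = softmax(logits.transpose(*perm), axis=-1)
    inv = list(np.argsort(perm))
    return p.transpose(*inv)


def one_hot(labels: np.ndarray, n_classes: int, class_axis: int = 0) -> np.ndarray:
    eye = np.eye(n_classes, dtype=np.float32)
    oh = eye[labels.astype(np.int64)]               # (..., n_classes)
    return np.moveaxis(oh, -1, class_axis)


def _check(p: Tensor, g: np.ndarray, class_axis: int):
    spatial = tuple(s for a, s in enumerate(p.shape) if a != class_axis)
    if spatial != tuple(g.shape):
        raise ValueError(f"probability/label shape mismatch: {p.shape} vs {g.shape}")


def dice_loss(p: Tensor, g: np.ndarray, class_axis: int = 1,
              classes=None, eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss averaged over the foreground classes.

    ``p`` holds per-class probabilities; ``g`` integer labels over the same
    spatial grid.  `classes` defaults to every class except background (0).
    """
    _check(p, g, class_axis)
    n_classes = p.shape[class_axis]
    if classes is None:
        classes = tuple(range(1, n_classes))
    g_oh = one_hot(g, n_classes, class_axis)
    total = None
    for c in classes:
        sl = [slice(None)] * p.ndim
        sl[class_axis] = c
        pc = p[tuple(sl)]
        gc = g_oh[tuple(sl)]
        inter = (pc * gc).sum()
        denom = pc.sum() + float(gc.sum())
        dice = (inter * 2.0 + eps) / (denom + eps)
        term = 1.0 - dice
        total = term if total is None else total + term
    return total * (1.0 / len(classes))


def cross_entropy_loss(p: Tensor, g: np.ndarray, class_axis: int = 1) -> Tensor:
    """Mean over voxels of -log p at the true class."""
    _check(p, g, class_axis)
    g_oh = one_hot(g, p.shape[class_axis], class_axis)
    p_true = (p * Tensor(g_oh)).sum(axis=class_axis)
    return -((p_true + _LOG_CLAMP).log().mean())


def combined_loss(p: Tensor, g: np.ndarray, alpha: float = 0.5,
                  beta: float = 0.5, class_axis: int = 1) -> Tensor:
    return dice_loss(p, g, class_axis) * alpha + \
        cross_entropy_loss(p, g, class_axis) * beta
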