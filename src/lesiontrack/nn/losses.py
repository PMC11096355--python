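"""Focal loss for imbalanced binary classification.

The focal loss down-weights well-classified examples by ``(1 - p_t)^gamma``
where ``p_t`` is the predicted probability of the true class, with a
per-class weight ``alpha`` (applied to positives; ``1 - alpha`` to
negatives).  With ``gamma=0`` and ``alpha=1`` it reduces exactly to
binary cross-entropy.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def focal_loss(p_true: np.ndarray, gamma: float, alpha: float = 1.0) -> float:
    """Mean focal loss from probabilities of the true class.

    ``p_true`` values of exactly 0 or 1 are clamped to ``1e-7`` away from
    the boundary before taking the logarithm.
    """
    p = np.clip(np.asarray(p_true, dtype=np.float64), _EPS, 1.0 - _EPS)
    return float(np.mean(-alpha * (1.0 - p) ** gamma * np.log(p)))


def focal_loss_with_logits(
    logits: np.ndarray, y: np.ndarray, gamma: float, alpha_pos: float
) -> tuple[float, np.ndarray]:
    """Mean focal loss and its gradient with respect to the logits.

    Positives are weighted by ``alpha_pos``, negatives by ``1 - alpha_pos``.
    """
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y)
    p = 1.0 / (1.0 + np.exp(-logits))
    pt = np.where(y == 1, p, 1.0 - p)
    pt = np.clip(pt, _EPS, 1.0 - _EPS)
    alpha_c = np.where(y == 1, alpha_pos, 1.0 - alpha_pos)
    one_m = 1.0 - pt
    loss = float(np.mean(-alpha_c * one_m**gamma * np.log(pt)))
    # dL/dpt, then chain through dpt/dlogit = +/- pt (1 - pt)
    # one_m is clamped >= eps, so the gamma-1 power stays finite; at
    # gamma == 0 the first term vanishes and the loss is cross-entropy
    dl_dpt = -alpha_c * (
        -gamma * one_m ** (gamma - 1.0) * np.log(pt) + one_m**gamma / pt
    )
    dpt_ds = pt * one_m * np.where(y == 1, 1.0, -1.0)
    grad = (dl_dpt * dpt_ds) / len(logits)
    return loss, grad.astype(np.float32)
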