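"""Classification losses for the raw-signal network.

Focal loss down-weights easy examples under class imbalance:
FL = -w_y (1 - p_y)^gamma log p_y, averaged over the batch; gamma = 0 with
unit weights reduces it to cross-entropy.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def focal_loss(
    probabilities: np.ndarray,
    true_class: np.ndarray,
    gamma: float = 2.0,
    class_weights: np.ndarray | None = None,
) -> float:
    """Mean focal loss over a batch of probability vectors."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(true_class, dtype=int)
    py = np.clip(p[np.arange(len(y)), y], _EPS, 1.0)
    w = np.ones(len(y)) if class_weights is None else np.asarray(class_weights)[y]
    return float(np.mean(-w * (1.0 - py) ** gamma * np.log(py)))


def cross_entropy_loss(
    probabilities: np.ndarray,
    true_class: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> float:
    return focal_loss(probabilities, true_class, gamma=0.0, class_weights=class_weights)


def focal_loss_grad_logits(
    probabilities: np.ndarray,
    true_class: np.ndarray,
    gamma: float,
    class_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Gradient of the mean focal loss with respect to the logits.

    With a = p_y:  dL/da = w [gamma (1-a)^(gamma-1) log a - (1-a)^gamma / a]
    and da/dz_j = a (delta_jy - p_j).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(true_class, dtype=int)
    n, _ = p.shape
    a = np.clip(p[np.arange(n), y], _EPS, 1.0 - _EPS)
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[y]
    if gamma == 0.0:
        dl_da = -w / a
    else:
        dl_da = w * (gamma * (1.0 - a) ** (gamma - 1.0) * np.log(a) - (1.0 - a) ** gamma / a)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    da_dz = a[:, None] * (onehot - p)
    return dl_da[:, None] * da_dz / n
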