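"""Loss functions for training under class imbalance.

Focal loss rescales the per-example cross-entropy by (1 - p_y)^gamma,
where p_y is the probability the model assigns to the true class, so
easy examples contribute little and training focuses on the hard ones.
The class-weight alternative multiplies the cross-entropy of positives
and negatives by fixed weights instead.

Conventions: labels are {1, 0} (mapping the +1/-1 convention of the
focal-loss literature as +1 -> 1, -1 -> 0); p is the predicted
probability of class 1; alpha weights class 1 and (1 - alpha) class 0,
so the default alpha = 0.25 downweights the minority positive class —
the standard focal-loss default, kept deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

#: probabilities are clamped to [EPS, 1-EPS] before taking logs
EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    kind: Literal["focal", "weighted_ce", "ce"] = "focal"
    gamma: float = 2.0
    alpha: float = 0.25
    class_weights: tuple[float, float] = (0.9, 0.1)  # (w_pos, w_neg)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if min(self.class_weights) < 0:
            raise ValueError("class weights must be nonnegative")


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def _p_true(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Probability assigned to the true class: p if y=1 else 1-p."""
    return np.where(y == 1, p, 1.0 - p)


def focal_loss(
    p: np.ndarray, y: np.ndarray, cfg: LossConfig = LossConfig()
) -> float:
    """Mean focal loss of a batch.

    L = (1 - p_y)^gamma * (-alpha_y * log p_y), with alpha_y = alpha for
    positives and 1 - alpha for negatives. gamma = 0 recovers the
    alpha-weighted cross-entropy.
    """
    p = _clamp(np.asarray(p, dtype=np.float64))
    y = np.asarray(y)
    p_y = _p_true(p, y)
    alpha_y = np.where(y == 1, cfg.alpha, 1.0 - cfg.alpha)
    ce = -alpha_y * np.log(p_y)
    return float(np.mean((1.0 - p_y) ** cfg.gamma * ce))


def weighted_ce(
    p: np.ndarray, y: np.ndarray, cfg: LossConfig = LossConfig()
) -> float:
    """Mean class-weighted cross-entropy: -w_y * log p_y."""
    p = _clamp(np.asarray(p, dtype=np.float64))
    y = np.asarray(y)
    p_y = _p_true(p, y)
    w_pos, w_neg = cfg.class_weights
    w_y = np.where(y == 1, w_pos, w_neg)
    return float(np.mean(-w_y * np.log(p_y)))


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Plain unweighted binary cross-entropy."""
    return weighted_ce(p, y, LossConfig(kind="ce", class_weights=(1.0, 1.0)))


def loss_value(p: np.ndarray, y: np.ndarray, cfg: LossConfig) -> float:
    if cfg.kind == "focal":
        return focal_loss(p, y, cfg)
    if cfg.kind == "weighted_ce":
        return weighted_ce(p, y, cfg)
    if cfg.kind == "ce":
        return weighted_ce(p, y, LossConfig(kind="ce", class_weights=(1.0, 1.0)))
    raise ValueError(f"unknown loss kind {cfg.kind!r}")


def loss_grad_wrt_p(p: np.ndarray, y: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """d(mean loss)/dp, elementwise, for backpropagation.

    Derivation for one example: with s = dp_y/dp = +1 (y=1) or -1 (y=0),
    dL/dp_y = w_y * [ gamma (1-p_y)^(gamma-1) log p_y - (1-p_y)^gamma / p_y ]
    for the focal case (gamma = 0 drops the first term), and
    dL/dp = s * dL/dp_y. Weighted CE is the gamma = 0 case with w_y
    taken from class_weights.
    """
    p = _clamp(np.asarray(p, dtype=np.float64))
    y = np.asarray(y)
    n = p.size
    p_y = _p_true(p, y)
    sign = np.where(y == 1, 1.0, -1.0)
    if cfg.kind == "focal":
        w_y = np.where(y == 1, cfg.alpha, 1.0 - cfg.alpha)
        gamma = cfg.gamma
    elif cfg.kind == "weighted_ce":
        w_y = np.where(y == 1, *cfg.class_weights)
        gamma = 0.0
    elif cfg.kind == "ce":
        w_y = np.ones_like(p)
        gamma = 0.0
    else:
        raise ValueError(f"unknown loss kind {cfg.kind!r}")

    one_minus = 1.0 - p_y
    d_py = -w_y * one_minus**gamma / p_y
    if gamma > 0:
        d_py = d_py + w_y * gamma * one_minus ** (gamma - 1.0) * np.log(p_y)
    return sign * d_py / n
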