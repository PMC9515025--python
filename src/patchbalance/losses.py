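"""Segmentation loss functions: CE, multi-class Dice, batch (nnU) Dice and
the class-adaptive Dice.

All losses operate on a softmax-normalized prediction tensor P[b, c, v] and
a one-hot ground-truth tensor G[b, c, v] with B batch items, C classes and
V voxels (tensors may also arrive as (B, C, X, Y, Z); the spatial axes are
flattened internally).

The four scores implemented here differ in how they treat the batch axis
and classes absent from a patch:

- ``cross_entropy``: mean voxel-wise negative log-likelihood of the true
  class.
- ``multiclass_dice``: the classical soft Dice averaged over all B*C
  (batch, class) pairs, with the stability constant eps in both numerator
  and denominator.  A class absent from prediction and ground truth
  contributes eps/eps = 1 — it is scored as perfectly segmented, which
  biases the average on patches with missing classes.
- ``nnu_dice``: the batch Dice — sums pooled jointly over batch and voxel
  axes, background excluded, averaged over the C-1 foreground classes.
  Pooling over the batch makes a class "present" if it appears anywhere in
  the batch, which reduces but does not remove the missing-class problem.
- ``ca_dice``: the class-adaptive Dice — per-(batch, class) terms with eps
  only in the denominator, restricted to the N pairs whose ground truth
  actually contains the class.  Absent classes are excluded from the
  average rather than scored 1, so the value equals the true soft Dice of
  the sampled patch.  When no counted class is present (N = 0) the score is
  undefined and the combined loss falls back to cross-entropy alone.

Dice scores are converted to losses as (1 - score) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

#: Floor for log arguments in the cross-entropy.
LOG_CLAMP = 1e-12


@dataclass(frozen=True)
class LossConfig:
    """Numeric and convention knobs shared by the loss family.

    epsilon : stability constant of the Dice denominators (and the
        numerator of the classical multi-class form).
    include_background_in_dice : whether ca-Dice counts the background
        class among its present-class terms (the batch Dice never does).
    ce_normalization : ``per_voxel`` divides the CE sum by B*V so its
        magnitude is patch-size invariant; ``per_batch`` divides by B only,
        the literal textbook scaling.
    dice_to_loss : ``one_minus`` maps a Dice score s to the loss 1 - s;
        ``negative`` maps it to -s.
    """

    epsilon: float = 1e-5
    include_background_in_dice: bool = False
    ce_normalization: str = "per_voxel"
    dice_to_loss: str = "one_minus"
    ce_weight: float = 1.0
    dice_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.ce_normalization not in ("per_voxel", "per_batch"):
            raise ValueError(f"unknown ce_normalization {self.ce_normalization!r}")
        if self.dice_to_loss not in ("one_minus", "negative"):
            raise ValueError(f"unknown dice_to_loss {self.dice_to_loss!r}")


class CaDiceResult(NamedTuple):
    """Class-adaptive Dice score and the number of counted (b, c) terms.

    ``score`` is ``nan`` when ``n_present`` is 0 (no counted class in the
    ground truth): the score is undefined, not zero."""

    score: float
    n_present: int

    @property
    def defined(self) -> bool:
        return self.n_present > 0


def _flatten(t: np.ndarray, name: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim == 3:
        return t
    if t.ndim == 5:
        return t.reshape(t.shape[0], t.shape[1], -1)
    raise ValueError(f"{name} must be (B, C, V) or (B, C, X, Y, Z), got shape {t.shape}")


def _check_pair(P: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = _flatten(P, "P")
    G = _flatten(G, "G")
    if P.shape != G.shape:
        raise ValueError(f"P shape {P.shape} != G shape {G.shape}")
    return P, G


def as_one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot encode an integer label array to (1, C, V)."""
    flat = np.asarray(labels).ravel()
    out = np.zeros((1, n_classes, flat.size))
    out[0, flat, np.arange(flat.size)] = 1.0
    return out


def cross_entropy(P: np.ndarray, G: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Multi-class cross-entropy -sum(G log P), normalized per voxel or per
    batch item.  Zero iff P assigns probability 1 to every true class."""
    P, G = _check_pair(P, G)
    total = -float(np.sum(G * np.log(np.maximum(P, LOG_CLAMP))))
    B, _, V = P.shape
    denom = B * V if cfg.ce_normalization == "per_voxel" else B
    return total / denom


def multiclass_dice(P: np.ndarray, G: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Classical multi-class soft Dice: mean over all B*C (batch, class)
    terms, background included, eps in numerator and denominator.

    A class with no support in either tensor scores eps/eps = 1."""
    P, G = _check_pair(P, G)
    eps = cfg.epsilon
    num = 2.0 * np.sum(P * G, axis=2) + eps
    den = np.sum(P, axis=2) + np.sum(G, axis=2) + eps
    return float(np.mean(num / den))


def nnu_dice(P: np.ndarray, G: np.ndarray, cfg: LossConfig = LossConfig()) -> float:
    """Batch Dice: sums pooled over batch and voxels jointly, background
    (class 0) excluded, averaged over the C-1 foreground classes."""
    P, G = _check_pair(P, G)
    if P.shape[1] < 2:
        raise ValueError("nnu_dice needs at least 2 classes")
    eps = cfg.epsilon
    num = 2.0 * np.sum(P * G, axis=(0, 2)) + eps
    den = np.sum(P, axis=(0, 2)) + np.sum(G, axis=(0, 2)) + eps
    return float(np.mean((num / den)[1:]))


def ca_dice(P: np.ndarray, G: np.ndarray, cfg: LossConfig = LossConfig()) -> CaDiceResult:
    """Class-adaptive Dice: per-(batch, class) soft Dice terms averaged over
    only the N pairs whose ground truth contains the class.

    eps appears only in the denominator; a counted pair's numerator is the
    bare overlap, so a predicted-but-absent class contributes nothing (the
    cross-entropy carries that penalty).  Background is excluded unless
    ``cfg.include_background_in_dice``.  With N = 0 the score is undefined:
    ``CaDiceResult(nan, 0)``.
    """
    P, G = _check_pair(P, G)
    eps = cfg.epsilon
    g_sums = np.sum(G, axis=2)  # (B, C)
    present = g_sums > 0
    if not cfg.include_background_in_dice:
        present = present.copy()
        present[:, 0] = False
    n_present = int(present.sum())
    if n_present == 0:
        return CaDiceResult(math.nan, 0)
    num = 2.0 * np.sum(P * G, axis=2)
    den = np.sum(P, axis=2) + g_sums + eps
    return CaDiceResult(float(np.mean((num / den)[present])), n_present)


def combined_loss(
    P: np.ndarray,
    G: np.ndarray,
    cfg: LossConfig = LossConfig(),
    dice_kind: str = "ca",
) -> float:
    """The CE+Dice training loss:
    ``ce_weight * CE + dice_weight * to_loss(Dice_variant)``.

    ``dice_kind`` selects the batch Dice (``nnu``) or the class-adaptive
    Dice (``ca``).  An undefined ca-Dice (no present class) contributes a
    zero Dice term, so the loss degrades gracefully to cross-entropy on
    background-only patches.
    """
    if dice_kind not in ("nnu", "ca"):
        raise ValueError(f"dice_kind must be 'nnu' or 'ca', got {dice_kind!r}")
    ce = cross_entropy(P, G, cfg) if cfg.ce_weight != 0 else 0.0
    if cfg.dice_weight == 0:
        return cfg.ce_weight * ce
    if dice_kind == "nnu":
        score = nnu_dice(P, G, cfg)
    else:
        result = ca_dice(P, G, cfg)
        if not result.defined:
            return cfg.ce_weight * ce
        score = result.score
    dice_term = (1.0 - score) if cfg.dice_to_loss == "one_minus" else -score
    return cfg.ce_weight * ce + cfg.dice_weight * dice_term
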