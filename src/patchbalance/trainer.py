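"""Desk-scale training demonstration.

Fits a compact voxel-classifier network on phantom data with the CE+Dice
losses to demonstrate, on CPU in minutes, that the loss family is
optimizable and to feed the confidence-drift analysis with real softmax
outputs.  It is a demonstration harness, not a segmentation architecture
study: full encoder-decoder training belongs on a GPU framework.

The model is a multiscale voxel classifier: a fixed Gaussian feature
pyramid over the image (raw intensity plus ``depth`` smoothed scales,
giving each voxel local context) concatenated with its normalized global
coordinates, followed by a trainable stack of 1x1x1 convolutions (an MLP
applied per voxel) with ReLU nonlinearities, hidden widths
``channels_base * 2**level``, and a softmax over the C classes.  Gradients
of the CE, batch-Dice and class-adaptive-Dice losses are computed
analytically and backpropagated through the stack; optimization is Adam.
Everything is plain numpy driven by one seeded generator, so a fixed seed
reproduces the loss curve bit-for-bit on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .losses import LOG_CLAMP, LossConfig, ca_dice, cross_entropy, nnu_dice
from .metrics import MetricConfig, MetricsReport, evaluate_case
from .sampling import PatchSpec, SamplerConfig, _foreground_index, sample_patch
from .volio import LabeledVolume


class TrainConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    patch: PatchSpec = PatchSpec((32, 32, 16))
    sampler: SamplerConfig = SamplerConfig("foreground_oversampled", 0.33, seed=0)
    loss: LossConfig = LossConfig()
    dice_kind: str = "ca"
    iterations: int = 300
    learning_rate: float = 0.05
    seed: int = 0
    channels_base: int = 8
    depth: int = 2

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise TrainConfigError("iterations must be >= 1")
        if self.dice_kind not in ("nnu", "ca"):
            raise TrainConfigError(f"dice_kind must be 'nnu' or 'ca', got {self.dice_kind!r}")
        div = 2**self.depth
        if any(p % div for p in self.patch.size):
            raise TrainConfigError(
                f"patch {self.patch.size} not divisible by 2**depth = {div}"
            )


# ---------------------------------------------------------------------------
# features


#: Intensity scale divisor bringing CT-like values to order 1.
INTENSITY_SCALE = 100.0


def _feature_volume(volume: LabeledVolume, depth: int) -> np.ndarray:
    """(F, X, Y, Z) feature stack: raw + ``depth`` Gaussian scales + coords."""
    img = volume.image.astype(float) / INTENSITY_SCALE
    feats = [img]
    for level in range(1, depth + 1):
        feats.append(ndimage.gaussian_filter(img, sigma=2.0**level))
    nx, ny, nz = volume.geometry.shape
    gx, gy, gz = np.meshgrid(
        np.linspace(0, 1, nx), np.linspace(0, 1, ny), np.linspace(0, 1, nz), indexing="ij"
    )
    feats.extend([gx, gy, gz])
    return np.stack(feats)


# ---------------------------------------------------------------------------
# model


@dataclass
class VoxelClassifier:
    """Per-voxel MLP (a 1x1x1 convolution stack) over precomputed features."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    depth: int

    @classmethod
    def init(
        cls, n_features: int, n_classes: int, channels_base: int, depth: int,
        rng: np.random.Generator,
    ) -> "VoxelClassifier":
        sizes = [n_features] + [channels_base * 2**lvl for lvl in range(depth)] + [n_classes]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return cls(weights=weights, biases=biases, depth=depth)

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """X (V, F) -> softmax probabilities (V, C); returns activations for
        backprop."""
        acts = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, acts

    def backward(
        self, acts: list[np.ndarray], dlogits: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradient of the loss w.r.t. weights/biases given d(loss)/d(logits)."""
        gw = [np.zeros_like(W) for W in self.weights]
        gb = [np.zeros_like(b) for b in self.biases]
        delta = dlogits
        for layer in range(len(self.weights) - 1, -1, -1):
            gw[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
        return gw, gb


# ---------------------------------------------------------------------------
# analytic loss gradients (w.r.t. the softmax output P, then the logits)


def _loss_and_grad_P(
    P: np.ndarray, G: np.ndarray, cfg: LossConfig, dice_kind: str
) -> tuple[float, np.ndarray]:
    """Combined loss and its gradient w.r.t. P, both on (B, C, V) tensors."""
    B, C, V = P.shape
    grad = np.zeros_like(P)
    total = 0.0
    if cfg.ce_weight != 0.0:
        ce = cross_entropy(P, G, cfg)
        denom = B * V if cfg.ce_normalization == "per_voxel" else B
        safe = np.maximum(P, LOG_CLAMP)
        grad += cfg.ce_weight * (-(G / safe) * (P > LOG_CLAMP)) / denom
        total += cfg.ce_weight * ce
    if cfg.dice_weight != 0.0:
        eps = cfg.epsilon
        if dice_kind == "nnu":
            score = nnu_dice(P, G, cfg)
            num = 2.0 * np.sum(P * G, axis=(0, 2)) + eps  # (C,)
            den = np.sum(P, axis=(0, 2)) + np.sum(G, axis=(0, 2)) + eps
            dscore = (2.0 * G * den[None, :, None] - num[None, :, None]) / den[
                None, :, None
            ] ** 2 / (C - 1)
            dscore[:, 0, :] = 0.0
            grad += cfg.dice_weight * (-dscore)
            total += cfg.dice_weight * (1.0 - score)
        else:
            result = ca_dice(P, G, cfg)
            if result.defined:
                g_sums = np.sum(G, axis=2)
                present = g_sums > 0
                if not cfg.include_background_in_dice:
                    present[:, 0] = False
                num = 2.0 * np.sum(P * G, axis=2)  # (B, C)
                den = np.sum(P, axis=2) + g_sums + eps
                dterm = (2.0 * G * den[:, :, None] - num[:, :, None]) / den[:, :, None] ** 2
                dterm[~present] = 0.0
                grad += cfg.dice_weight * (-dterm / result.n_present)
                total += cfg.dice_weight * (1.0 - result.score)
    return total, grad


def _grad_logits(P_vc: np.ndarray, gP_vc: np.ndarray) -> np.ndarray:
    """Chain d(loss)/dP through the per-voxel softmax Jacobian.

    Both arguments are (V, C); returns d(loss)/d(logits), (V, C)."""
    inner = (gP_vc * P_vc).sum(axis=1, keepdims=True)
    return P_vc * (gP_vc - inner)


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainResult:
    model: VoxelClassifier
    loss_curve: np.ndarray
    report: MetricsReport
    config: TrainConfig = field(repr=False, default=None)


def predict_probabilities(
    model: VoxelClassifier, volume: LabeledVolume
) -> np.ndarray:
    """Softmax class probabilities (C, X, Y, Z) for a whole volume."""
    feats = _feature_volume(volume, model.depth)
    X = feats.reshape(feats.shape[0], -1).T
    probs, _ = model.forward(X)
    return probs.T.reshape((probs.shape[1],) + volume.geometry.shape)


def train_demo(
    dataset: Sequence[LabeledVolume],
    cfg: TrainConfig = TrainConfig(),
    eval_dataset: Sequence[LabeledVolume] | None = None,
    metric_cfg: MetricConfig = MetricConfig(),
) -> TrainResult:
    """Patch-sampled optimization of the configured CE+Dice loss.

    One patch is drawn per iteration with the configured sampler, the
    combined loss evaluated on the model's softmax output, and the analytic
    gradient applied with Adam.  Returns the per-iteration loss values and
    a metrics report on ``eval_dataset`` (default: the training volumes).

    With ``ce_weight = dice_weight = 0`` the gradient is identically zero
    and the parameters stay at their initialization (flat loss curve at 0).
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must be non-empty")
    n_classes = max(v.n_classes for v in dataset)
    feats = [_feature_volume(v, cfg.depth) for v in dataset]
    onehots = [np.eye(n_classes)[v.labels] for v in dataset]  # (X,Y,Z,C)
    fg_index = [_foreground_index(v.labels) for v in dataset]

    rng = np.random.default_rng(cfg.seed)
    model = VoxelClassifier.init(
        feats[0].shape[0], n_classes, cfg.channels_base, cfg.depth, rng
    )
    sampler_rng = np.random.default_rng(cfg.sampler.seed)

    # Adam state
    m_w = [np.zeros_like(W) for W in model.weights]
    v_w = [np.zeros_like(W) for W in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8

    curve = np.empty(cfg.iterations)
    for it in range(cfg.iterations):
        vi = int(sampler_rng.integers(len(dataset)))
        volume = dataset[vi]
        corner = sample_patch(
            volume.labels, cfg.patch, cfg.sampler, sampler_rng, fg_index=fg_index[vi]
        )
        size = cfg.patch.clipped_to(volume.labels.shape)
        sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
        X = feats[vi][(slice(None),) + sl].reshape(feats[vi].shape[0], -1).T  # (V, F)
        G_vc = onehots[vi][sl].reshape(-1, n_classes)  # (V, C)

        probs, acts = model.forward(X)  # (V, C)
        P3 = probs.T[None]  # (1, C, V)
        G3 = G_vc.T[None]
        loss, gP = _loss_and_grad_P(P3, G3, cfg.loss, cfg.dice_kind)
        curve[it] = loss
        dlogits = _grad_logits(probs, gP[0].T)
        gw, gb = model.backward(acts, dlogits)

        t = it + 1
        for i in range(len(model.weights)):
            m_w[i] = beta1 * m_w[i] + (1 - beta1) * gw[i]
            v_w[i] = beta2 * v_w[i] + (1 - beta2) * gw[i] ** 2
            m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb[i]
            v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb[i] ** 2
            mw_hat = m_w[i] / (1 - beta1**t)
            vw_hat = v_w[i] / (1 - beta2**t)
            mb_hat = m_b[i] / (1 - beta1**t)
            vb_hat = v_b[i] / (1 - beta2**t)
            model.weights[i] -= cfg.learning_rate * mw_hat / (np.sqrt(vw_hat) + adam_eps)
            model.biases[i] -= cfg.learning_rate * mb_hat / (np.sqrt(vb_hat) + adam_eps)

    eval_set = list(eval_dataset) if eval_dataset is not None else dataset
    tables = []
    for volume in eval_set:
        probs = predict_probabilities(model, volume)
        pred = probs.argmax(axis=0)
        report = evaluate_case(
            pred, volume.labels, volume.geometry, metric_cfg,
            class_names=list(volume.class_names),
        )
        tables.append(report.table)
    import pandas as pd

    merged = MetricsReport(table=pd.concat(tables, ignore_index=True))
    return TrainResult(model=model, loss_curve=curve, report=merged, config=cfg)
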