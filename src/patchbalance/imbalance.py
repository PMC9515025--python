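"""The sigma class-imbalance statistic and patch-size optimization.

The in-patch class distribution a segmentation loss is trained on depends
on the patch size.  To compare candidate sizes with a single number, each
sampled patch's class counts are normalized to ratios, the ratios are
averaged over an epoch of patches (average of ratios, not ratio of pooled
sums), and the population standard deviation of the C averaged ratios —
background included — is reported as sigma.  Because the averaged ratios
sum to one, sigma is exactly the average distance of the epoch's class
distribution from the ideal uniform distribution (ratio 1/C everywhere):
sigma = 0 iff every class receives equal share, and sigma grows toward its
upper bound sqrt(C-1)/C < 1 as one class dominates.  Minimizing sigma over
candidate patch sizes selects the training window with the least class
imbalance for a given dataset and sampling strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sampling import DEFAULT_EPOCH_PATCHES, PatchSpec, SamplerConfig, simulate_epoch
from .volio import LabeledVolume

RATIO_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ClassRatioProfile:
    """Epoch-averaged in-patch class ratios."""

    ratios: tuple[float, ...]
    n_patches: int
    patch: PatchSpec | None = None
    strategy: str | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if r.size < 2:
            raise ValueError("a ratio profile needs at least 2 classes")
        if (r < -RATIO_SUM_TOL).any() or (r > 1 + RATIO_SUM_TOL).any():
            raise ValueError(f"ratios must lie in [0, 1], got {self.ratios}")
        if abs(r.sum() - 1.0) > 1e-6:
            raise ValueError(f"ratios must sum to 1, got sum {r.sum()}")
        object.__setattr__(self, "ratios", tuple(float(x) for x in r))

    @property
    def n_classes(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class ImbalanceResult:
    """sigma together with the profile it was computed from."""

    sigma: float
    profile: ClassRatioProfile
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma < 1.0:
            raise ValueError(f"sigma must lie in [0, 1), got {self.sigma}")


def class_ratios(
    count_vectors: Sequence[Sequence[int]],
    patch: PatchSpec | None = None,
    strategy: str | None = None,
) -> ClassRatioProfile:
    """Average the per-patch class ratios over an epoch of count vectors.

    Each patch's integer counts are normalized by the patch voxel count
    first; the resulting ratio vectors are then averaged across patches.
    This is the average of ratios, not the ratio of pooled sums: a small
    patch dominated by a rare organ carries the same weight as a large one.
    """
    counts = np.asarray(count_vectors, dtype=float)
    if counts.ndim != 2:
        raise ValueError("count vectors must all have the same length")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    sums = counts.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("every count vector must have a positive sum")
    ratios = (counts / sums[:, None]).mean(axis=0)
    ratios = ratios / ratios.sum()  # renormalize away float rounding
    return ClassRatioProfile(
        ratios=tuple(ratios), n_patches=counts.shape[0], patch=patch, strategy=strategy
    )


def imbalance_sigma(profile: ClassRatioProfile | Sequence[float]) -> float:
    """Population standard deviation (divisor C) of the averaged class ratios.

    Background is included among the C classes.  Returns 0 iff the ratios
    are uniform (all 1/C)."""
    ratios = profile.ratios if isinstance(profile, ClassRatioProfile) else profile
    r = np.asarray(ratios, dtype=float)
    return float(np.sqrt(np.mean((r - r.mean()) ** 2)))


def whole_volume_profile(volume: LabeledVolume) -> ClassRatioProfile:
    """Whole-volume class ratios of a single labeled volume."""
    counts = np.bincount(volume.labels.ravel(), minlength=volume.n_classes)
    return class_ratios([counts], strategy="whole_image")


def epoch_imbalance(
    dataset: Sequence[LabeledVolume],
    patch: PatchSpec,
    cfg: SamplerConfig,
    n_patches: int = DEFAULT_EPOCH_PATCHES,
) -> ImbalanceResult:
    """sigma of one simulated epoch: sample patches, average ratios, take sigma."""
    counts = simulate_epoch(dataset, patch, cfg, n_patches)
    profile = class_ratios(counts, patch=patch, strategy=cfg.strategy)
    return ImbalanceResult(sigma=imbalance_sigma(profile), profile=profile, seed=cfg.seed)


def candidate_patch_sizes(
    dataset: Sequence[LabeledVolume],
    min_size: tuple[int, int, int] = (8, 8, 8),
    depth: int = 3,
    include_whole_image: bool = False,
) -> list[PatchSpec]:
    """Divisor-friendly candidate sizes between ``min_size`` and the dataset
    median shape.

    Every component is a multiple of ``2**depth`` (the U-Net downsampling
    constraint: a patch must survive ``depth`` halvings), obtained by
    doubling from ``min_size`` until the median shape is exceeded, with the
    median shape itself (rounded down to the divisor) as the last entry.
    """
    shapes = np.asarray([v.geometry.shape for v in dataset])
    median = np.median(shapes, axis=0)
    div = 2**depth
    candidates: list[tuple[int, int, int]] = []
    size = np.maximum(np.asarray(min_size), 1)
    size = np.maximum((np.ceil(size / div) * div).astype(int), div)
    while (size <= median).all():
        candidates.append(tuple(int(s) for s in size))
        size = size * 2
    capped = tuple(int(max(div, (m // div) * div)) for m in median)
    if capped not in candidates:
        candidates.append(capped)
    if include_whole_image:
        whole = tuple(int(m) for m in median)
        if whole not in candidates:
            candidates.append(whole)
    return [PatchSpec(c) for c in candidates]


def optimize_patch_size(
    dataset: Sequence[LabeledVolume],
    candidates: Sequence[PatchSpec],
    cfg: SamplerConfig,
    n_patches: int = DEFAULT_EPOCH_PATCHES,
) -> tuple[PatchSpec, pd.DataFrame]:
    """Evaluate sigma for every candidate patch size and pick the minimum.

    All candidates share the same base seed so they see identical sampling
    randomness.  Ties break toward the larger patch volume (more spatial
    context at equal imbalance).  Returns the winner and the full table
    sorted ascending by sigma, one row per candidate with columns
    ``px, py, pz, sigma, n_patches, seed``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    rows = []
    for cand in candidates:
        result = epoch_imbalance(dataset, cand, cfg, n_patches)
        rows.append(
            {
                "px": cand.size[0],
                "py": cand.size[1],
                "pz": cand.size[2],
                "sigma": result.sigma,
                "n_patches": n_patches,
                "seed": cfg.seed,
                "patch_volume": cand.volume,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["sigma", "patch_volume"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    best = PatchSpec((int(order.px[0]), int(order.py[0]), int(order.pz[0])))
    return best, order.drop(columns="patch_volume")
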