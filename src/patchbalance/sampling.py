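"""Patch sampling strategies for patch-based segmentation training.

Patch-based training optimizes on randomly sampled sub-volumes because a
full 3D CT does not fit in GPU memory.  How those patches are drawn sets
the class distribution the loss actually sees, so this module implements
the strategies whose in-patch imbalance the toolkit compares:

- ``whole_image``: the degenerate strategy, every "patch" is the volume;
- ``uniform_random``: corners uniform over all valid positions;
- ``foreground_oversampled``: with probability ``oversample_fraction``
  (default 0.33, the common 33 % foreground-oversampling rule) the patch
  is centred on a uniformly chosen voxel of a uniformly chosen foreground
  class present in the volume, then clipped to bounds; otherwise uniform.

All randomness flows through an explicit ``numpy.random.Generator``; there
is no global state.  Patches larger than the volume are clipped, never
padded, so ratio measurements reflect real image content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volio import LabeledVolume

logger = logging.getLogger("patchbalance")

STRATEGIES = ("whole_image", "uniform_random", "foreground_oversampled")

#: Default number of patches per simulated epoch (250 iterations x batch 2).
DEFAULT_EPOCH_PATCHES = 500


@dataclass(frozen=True)
class PatchSpec:
    """A candidate training-window size in voxels."""

    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.size) != 3 or any(int(s) < 1 for s in self.size):
            raise ValueError(f"patch size components must be >= 1, got {self.size}")
        object.__setattr__(self, "size", tuple(int(s) for s in self.size))

    @property
    def volume(self) -> int:
        return int(np.prod(self.size))

    def clipped_to(self, shape: Sequence[int]) -> tuple[int, int, int]:
        """Effective patch size inside a volume of the given shape."""
        return tuple(min(p, int(n)) for p, n in zip(self.size, shape))


@dataclass(frozen=True)
class SamplerConfig:
    strategy: str = "uniform_random"
    oversample_fraction: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if not 0.0 <= self.oversample_fraction <= 1.0:
            raise ValueError(
                f"oversample_fraction must be in [0, 1], got {self.oversample_fraction}"
            )


def _foreground_index(labels: np.ndarray) -> dict[int, np.ndarray]:
    """Map each foreground class present in ``labels`` to its flat voxel indices."""
    index: dict[int, np.ndarray] = {}
    flat = labels.ravel()
    for value in np.unique(flat):
        if value > 0:
            index[int(value)] = np.flatnonzero(flat == value)
    return index


_warned_background_only = False


def sample_patch(
    labels: np.ndarray,
    patch: PatchSpec,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    fg_index: dict[int, np.ndarray] | None = None,
) -> tuple[int, int, int]:
    """Draw one patch corner.

    Returns the 0-based corner of the half-open box
    ``[corner, corner + clipped_size)``.  ``fg_index`` optionally caches
    :func:`_foreground_index` for repeated draws from the same volume.
    """
    global _warned_background_only
    shape = labels.shape
    size = patch.clipped_to(shape)
    if cfg.strategy == "whole_image":
        return (0, 0, 0)
    if cfg.strategy == "foreground_oversampled" and rng.random() < cfg.oversample_fraction:
        if fg_index is None:
            fg_index = _foreground_index(labels)
        if fg_index:
            cls = int(rng.choice(sorted(fg_index)))
            voxels = fg_index[cls]
            center = np.unravel_index(int(voxels[rng.integers(len(voxels))]), shape)
            corner = tuple(
                int(np.clip(c - s // 2, 0, n - s))
                for c, s, n in zip(center, size, shape)
            )
            return corner
        if not _warned_background_only:
            logger.warning(
                "foreground oversampling requested on a background-only volume; "
                "falling back to uniform sampling"
            )
            _warned_background_only = True
    # uniform over valid corners
    return tuple(int(rng.integers(0, n - s + 1)) for s, n in zip(size, shape))


def patch_class_counts(
    labels: np.ndarray, corner: Sequence[int], size: Sequence[int], n_classes: int
) -> np.ndarray:
    """Integer label histogram (length ``n_classes``) inside one patch."""
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    return np.bincount(labels[sl].ravel(), minlength=n_classes)


def simulate_epoch(
    dataset: Sequence[LabeledVolume],
    patch: PatchSpec,
    cfg: SamplerConfig,
    n_patches: int = DEFAULT_EPOCH_PATCHES,
) -> list[np.ndarray]:
    """Simulate one training epoch of patch sampling.

    Draws ``n_patches`` patches, choosing a volume uniformly at random for
    each, and returns the per-patch class-count vectors (length C, C taken
    from the dataset's class vocabulary).  Deterministic under the config
    seed.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must be non-empty")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    n_classes = max(v.n_classes for v in dataset)
    rng = np.random.default_rng(cfg.seed)
    fg_cache: list[dict[int, np.ndarray] | None] = [None] * len(dataset)
    counts = []
    for _ in range(n_patches):
        vi = int(rng.integers(len(dataset)))
        volume = dataset[vi]
        if cfg.strategy == "foreground_oversampled" and fg_cache[vi] is None:
            fg_cache[vi] = _foreground_index(volume.labels)
        corner = sample_patch(volume.labels, patch, cfg, rng, fg_index=fg_cache[vi])
        size = patch.clipped_to(volume.labels.shape)
        counts.append(patch_class_counts(volume.labels, corner, size, n_classes))
    return counts
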