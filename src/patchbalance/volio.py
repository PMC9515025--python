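"""Labeled-volume I/O, the dataset spacing rule, and resampling.

Volumes are held in (x, y, z) index order with 0-based indices; spacing,
origin and all distances are in millimetres.  NIfTI (.nii/.nii.gz) and NRRD
(.nrrd) are supported through SimpleITK.  Direction matrices are read but
never applied: the toolkit assumes axis-aligned volumes (the bundled
phantoms are) and logs a warning otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

logger = logging.getLogger("patchbalance")

#: Tolerance for deciding a floating-point label file holds integers.
LABEL_INT_TOL = 1e-6
#: Spacing round-trip tolerance in mm.
SPACING_TOL = 1e-6


class VolumeFormatError(ValueError):
    """Raised for unreadable or unsupported volume files."""


class VolumeValidationError(ValueError):
    """Raised when a file's content violates the label/geometry contract."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Physical geometry of a 3D volume.

    Parameters
    ----------
    spacing : tuple of float
        (sx, sy, sz) voxel size in mm; all positive.
    origin : tuple of float
        (ox, oy, oz) position of voxel (0, 0, 0) in mm.
    shape : tuple of int
        (nx, ny, nz) voxel counts; all >= 1.
    """

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 counts >= 1, got {self.shape}")
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))


@dataclass
class LabeledVolume:
    """A 3D image with an integer label map and physical geometry.

    ``image`` is a Hounsfield-unit-like scalar array, ``labels`` an integer
    array with values in {0..C-1} where index 0 is background.  Both share
    ``geometry.shape``.
    """

    image: np.ndarray
    labels: np.ndarray
    geometry: VolumeGeometry
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.labels = np.asarray(self.labels)
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image shape {self.image.shape} != labels shape {self.labels.shape}"
            )
        if tuple(self.image.shape) != self.geometry.shape:
            raise ValueError(
                f"array shape {self.image.shape} != geometry.shape {self.geometry.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if not self.class_names:
            c = int(self.labels.max()) + 1 if self.labels.size else 1
            self.class_names = [f"class_{i}" for i in range(c)]
        if self.labels.size and int(self.labels.max()) >= len(self.class_names):
            raise ValueError(
                f"label value {int(self.labels.max())} out of range for "
                f"{len(self.class_names)} classes"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format: {path} (expected .nii, .nii.gz or .nrrd)"
        )


def read_volume(path: str | Path, kind: str = "image") -> tuple[np.ndarray, VolumeGeometry]:
    """Read a NIfTI or NRRD volume.

    Parameters
    ----------
    path : str or Path
    kind : {"image", "labels"}
        Label volumes are validated and cast to integer.

    Returns
    -------
    array : ndarray in (x, y, z) index order
    geometry : VolumeGeometry with spacing in mm
    """
    path = Path(path)
    if kind not in ("image", "labels"):
        raise ValueError(f"kind must be 'image' or 'labels', got {kind!r}")
    if not path.exists():
        raise VolumeFormatError(f"file not found: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - SimpleITK raises RuntimeError
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        logger.warning("%s: non-identity direction matrix; axes are NOT reoriented", path)
    # SimpleITK arrays arrive as (z, y, x); transpose to (x, y, z).
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    geometry = VolumeGeometry(
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        shape=arr.shape,
    )
    if kind == "labels":
        if np.issubdtype(arr.dtype, np.floating):
            rounded = np.rint(arr)
            if np.abs(arr - rounded).max(initial=0.0) > LABEL_INT_TOL:
                raise VolumeValidationError(
                    f"{path}: label values deviate from integers by more than {LABEL_INT_TOL}"
                )
            arr = rounded
        arr = arr.astype(np.int32)
    return arr, geometry


def write_volume(array: np.ndarray, geometry: VolumeGeometry, path: str | Path) -> None:
    """Write an (x, y, z) array with its geometry as NIfTI or NRRD."""
    path = Path(path)
    _check_suffix(path)
    array = np.asarray(array)
    if tuple(array.shape) != geometry.shape:
        raise ValueError(f"array shape {array.shape} != geometry.shape {geometry.shape}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetSpacing(geometry.spacing)
    img.SetOrigin(geometry.origin)
    sitk.WriteImage(img, str(path))


def read_labeled_volume(
    image_path: str | Path,
    labels_path: str | Path,
    class_names: Sequence[str] | None = None,
) -> LabeledVolume:
    """Read a matching image/labels pair into a :class:`LabeledVolume`."""
    image, geom_i = read_volume(image_path, kind="image")
    labels, geom_l = read_volume(labels_path, kind="labels")
    if geom_i.shape != geom_l.shape:
        raise VolumeValidationError(
            f"image shape {geom_i.shape} != labels shape {geom_l.shape}"
        )
    if max(abs(a - b) for a, b in zip(geom_i.spacing, geom_l.spacing)) > SPACING_TOL:
        raise VolumeValidationError(
            f"image spacing {geom_i.spacing} != labels spacing {geom_l.spacing}"
        )
    return LabeledVolume(
        image=image,
        labels=labels,
        geometry=geom_i,
        class_names=list(class_names) if class_names else [],
    )


def compute_target_spacing(
    spacings: Sequence[tuple[float, float, float]],
) -> tuple[float, float, float]:
    """Dataset resampling target: median in-plane spacing, 10th-percentile
    out-plane spacing.

    In-plane means the first two axes (x, y), out-plane the third (z).  The
    10th percentile uses linear interpolation between order statistics.

    Returns
    -------
    (sx, sy, sz) in mm.
    """
    spacings = list(spacings)
    if not spacings:
        raise ValueError("spacings list must be non-empty")
    arr = np.asarray(spacings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected a list of (sx, sy, sz) triples, got shape {arr.shape}")
    if (arr <= 0).any():
        raise ValueError("all spacing components must be positive")
    sx = float(np.median(arr[:, 0]))
    sy = float(np.median(arr[:, 1]))
    sz = float(np.percentile(arr[:, 2], 10, method="linear"))
    return (sx, sy, sz)


def resample(volume: LabeledVolume, target: Sequence[float]) -> LabeledVolume:
    """Resample a labeled volume to a target spacing.

    New shape is ``round(old_shape * old_spacing / target)`` (>= 1 per axis).
    The image is interpolated linearly, labels with nearest neighbour, so no
    label value absent from the input can appear in the output.
    """
    target = tuple(float(t) for t in target)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be 3 positive reals, got {target}")
    old_spacing = volume.geometry.spacing
    old_shape = volume.geometry.shape
    new_shape = tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(old_shape, old_spacing, target)
    )
    if new_shape == old_shape and max(abs(a - b) for a, b in zip(old_spacing, target)) <= SPACING_TOL:
        image, labels = volume.image.copy(), volume.labels.copy()
    else:
        zoom = [n_new / n_old for n_new, n_old in zip(new_shape, old_shape)]
        # grid_mode treats voxels as cells so integer upsampling expands each
        # voxel into an exact block under nearest-neighbour interpolation.
        image = ndimage.zoom(
            volume.image.astype(float), zoom, order=1, mode="nearest", grid_mode=True
        )
        labels = ndimage.zoom(
            volume.labels, zoom, order=0, mode="nearest", grid_mode=True
        )
        assert image.shape == new_shape, (image.shape, new_shape)
    geometry = replace(volume.geometry, spacing=target, shape=new_shape)
    return LabeledVolume(
        image=image, labels=labels, geometry=geometry, class_names=list(volume.class_names)
    )
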