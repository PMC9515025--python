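"""Train/test softmax-confidence analysis.

After softmax normalization, a segmentation network's per-voxel class
probability is its confidence.  For an under-represented class the
confidence distribution tends to sit high on training data but slide
toward the decision boundary on unseen data; the gap between the two mean
confidences — the drift — flags class-wise overfitting without needing a
logit-space decision-boundary plot (which only exists for up to three
classes).

Confidences are read at the ground-truth voxels of each organ by default,
which makes the measure independent of the model's own decisions; reading
at predicted voxels is available via ``voxel_set="predicted"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("patchbalance")


@dataclass
class ConfidenceSummary:
    """Per-organ train/test confidence samples and their mean drift."""

    organ: str
    train_confidences: np.ndarray
    test_confidences: np.ndarray

    @property
    def drift(self) -> float:
        """mean(train) - mean(test); positive when the model is more
        confident on training data (the overfitting signature)."""
        if len(self.train_confidences) == 0 or len(self.test_confidences) == 0:
            return float("nan")
        return float(np.mean(self.train_confidences) - np.mean(self.test_confidences))


def organ_confidences(
    softmax_volume: np.ndarray,
    ref_labels: np.ndarray,
    organ_id: int,
    pred_labels: np.ndarray | None = None,
    voxel_set: str = "reference",
) -> np.ndarray:
    """Softmax probabilities of class ``organ_id`` at that organ's voxels.

    Parameters
    ----------
    softmax_volume : (C, X, Y, Z) or (C, V) per-class probability volume,
        normalized per voxel.
    ref_labels : integer label volume defining the organ's voxel set.
    organ_id : foreground class index (>= 1).
    voxel_set : "reference" reads at ground-truth voxels (default);
        "predicted" at the voxels argmax-assigned to the organ
        (``pred_labels`` overrides the argmax if given).

    Returns the raw probability values (no transformation beyond
    selection); empty when the organ is absent from the chosen voxel set.
    """
    if organ_id < 1:
        raise ValueError("organ_id must be >= 1 (0 is background)")
    probs = np.asarray(softmax_volume, dtype=float)
    labels = np.asarray(ref_labels)
    probs_flat = probs.reshape(probs.shape[0], -1)
    if organ_id >= probs.shape[0]:
        raise ValueError(f"organ_id {organ_id} out of range for {probs.shape[0]} classes")
    if probs_flat.shape[1] != labels.size:
        raise ValueError("probability volume and label volume sizes differ")
    if voxel_set == "reference":
        sel = labels.ravel() == organ_id
    elif voxel_set == "predicted":
        assigned = (
            np.asarray(pred_labels).ravel()
            if pred_labels is not None
            else probs_flat.argmax(axis=0)
        )
        sel = assigned == organ_id
    else:
        raise ValueError(f"voxel_set must be 'reference' or 'predicted', got {voxel_set!r}")
    values = probs_flat[organ_id, sel]
    if values.size == 0:
        logger.warning("organ %d absent from the %s voxel set", organ_id, voxel_set)
    return values


def confidence_drift(
    train_lists: dict[str, np.ndarray],
    test_lists: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-organ mean confidence drift mean(train) - mean(test).

    Returns
    -------
    drift_table : one row per organ with train/test means, counts and drift
        (nan + a warning when one side is empty).
    long_table : long-format (organ, split, confidence) rows for
        violin-style plotting.
    """
    organs = sorted(set(train_lists) | set(test_lists))
    rows, long_rows = [], []
    for organ in organs:
        tr = np.asarray(train_lists.get(organ, []), dtype=float)
        te = np.asarray(test_lists.get(organ, []), dtype=float)
        summary = ConfidenceSummary(organ, tr, te)
        if len(tr) == 0 or len(te) == 0:
            logger.warning("organ %r has an empty train or test confidence list", organ)
        rows.append(
            {
                "organ": organ,
                "train_mean": float(np.mean(tr)) if len(tr) else float("nan"),
                "test_mean": float(np.mean(te)) if len(te) else float("nan"),
                "n_train": len(tr),
                "n_test": len(te),
                "drift": summary.drift,
            }
        )
        long_rows.extend(
            {"organ": organ, "split": "train", "confidence": float(v)} for v in tr
        )
        long_rows.extend(
            {"organ": organ, "split": "test", "confidence": float(v)} for v in te
        )
    return pd.DataFrame(rows), pd.DataFrame(long_rows)
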