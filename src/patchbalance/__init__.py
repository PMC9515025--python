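"""patchbalance: class-imbalance tooling for patch-based 3D segmentation.

Measures the in-patch class imbalance of a labeled-volume dataset with the
sigma statistic (population standard deviation of epoch-averaged in-patch
class ratios), optimizes the training patch size by minimizing sigma,
implements the CE / multi-class Dice / batch Dice / class-adaptive Dice
loss family, the standard evaluation metrics (volumetric Dice, 95 %
Hausdorff distance, surface Dice), a train/test softmax-confidence drift
analysis, and a synthetic multi-organ phantom generator plus a desk-scale
trainer so the whole pipeline runs without external data.
"""

from .confidence import ConfidenceSummary, confidence_drift, organ_confidences
from .imbalance import (
    ClassRatioProfile,
    ImbalanceResult,
    candidate_patch_sizes,
    class_ratios,
    epoch_imbalance,
    imbalance_sigma,
    optimize_patch_size,
    whole_volume_profile,
)
from .losses import (
    CaDiceResult,
    LossConfig,
    as_one_hot,
    ca_dice,
    combined_loss,
    cross_entropy,
    multiclass_dice,
    nnu_dice,
)
from .metrics import (
    MetricConfig,
    MetricsReport,
    dice_score,
    evaluate_case,
    hausdorff95,
    surface_dice,
    surface_voxels,
)
from .phantom import (
    OrganSpec,
    PhantomConfig,
    generate_phantom,
    han_like_preset,
    phantom_dataset,
)
from .sampling import (
    DEFAULT_EPOCH_PATCHES,
    PatchSpec,
    SamplerConfig,
    patch_class_counts,
    sample_patch,
    simulate_epoch,
)
from .trainer import TrainConfig, TrainResult, predict_probabilities, train_demo
from .volio import (
    LabeledVolume,
    VolumeGeometry,
    compute_target_spacing,
    read_labeled_volume,
    read_volume,
    resample,
    write_volume,
)

__version__ = "0.1.0"

__all__ = [
    "CaDiceResult",
    "ClassRatioProfile",
    "ConfidenceSummary",
    "DEFAULT_EPOCH_PATCHES",
    "ImbalanceResult",
    "LabeledVolume",
    "LossConfig",
    "MetricConfig",
    "MetricsReport",
    "OrganSpec",
    "PatchSpec",
    "PhantomConfig",
    "SamplerConfig",
    "TrainConfig",
    "TrainResult",
    "VolumeGeometry",
    "as_one_hot",
    "ca_dice",
    "candidate_patch_sizes",
    "class_ratios",
    "combined_loss",
    "compute_target_spacing",
    "confidence_drift",
    "cross_entropy",
    "dice_score",
    "epoch_imbalance",
    "evaluate_case",
    "generate_phantom",
    "han_like_preset",
    "hausdorff95",
    "imbalance_sigma",
    "multiclass_dice",
    "nnu_dice",
    "optimize_patch_size",
    "organ_confidences",
    "patch_class_counts",
    "phantom_dataset",
    "predict_probabilities",
    "read_labeled_volume",
    "read_volume",
    "resample",
    "sample_patch",
    "simulate_epoch",
    "surface_dice",
    "surface_voxels",
    "train_demo",
    "whole_volume_profile",
    "write_volume",
]
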