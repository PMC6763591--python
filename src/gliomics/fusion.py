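"""Semantic label fusion of two multi-class segmentations and Dice evaluation.

Fusion unions the per-class binary masks of two competing segmentations
(e.g., the outputs of two independently trained segmenters).  The union
preserves specificity while improving sensitivity: any voxel either input
marks abnormal stays abnormal.  Where the inputs disagree on the class of a
voxel, the most specific tissue wins (ET > necrosis > edema), which keeps the
evaluation hierarchy WT >= TC >= ET intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gliomics.io import GeometryError, TissueLabelMap, derive_region

# conflict precedence, most specific tissue first
_PRECEDENCE = (4, 1, 2)  # ET, necrosis, edema


@dataclass(frozen=True)
class FusionResult:
    fused: TissueLabelMap
    input_a: TissueLabelMap
    input_b: TissueLabelMap


@dataclass(frozen=True)
class DiceReport:
    enhancing_tumor: float
    whole_tumor: float
    tumor_core: float

    def as_dict(self) -> dict[str, float]:
        return {
            "dice_enhancing_tumor": self.enhancing_tumor,
            "dice_whole_tumor": self.whole_tumor,
            "dice_tumor_core": self.tumor_core,
        }


def _check_same_geometry(a, b) -> None:
    if a.shape != b.shape:
        raise GeometryError(f"geometry mismatch: {a.shape} vs {b.shape}")


def fuse_labels(a: TissueLabelMap, b: TissueLabelMap) -> FusionResult:
    """Union the per-class masks of two label maps.

    Voxels claimed by different classes are resolved by the fixed precedence
    ET > necrosis > edema; background only where both inputs are background.
    """
    _check_same_geometry(a, b)
    fused = np.zeros_like(a.labels)
    for code in reversed(_PRECEDENCE):  # least specific written first, overwritten
        fused[(a.labels == code) | (b.labels == code)] = code
    return FusionResult(
        TissueLabelMap(fused, spacing=a.spacing, affine=a.affine), a, b
    )


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """DSC = 2|a & b| / (|a| + |b|); 1.0 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    _check_same_geometry(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def region_dice_report(pred: TissueLabelMap, truth: TissueLabelMap) -> DiceReport:
    """Dice over the three BraTS evaluation regions (ET, WT, TC)."""
    _check_same_geometry(pred, truth)
    return DiceReport(
        enhancing_tumor=dice_score(derive_region(pred, "ET"), derive_region(truth, "ET")),
        whole_tumor=dice_score(derive_region(pred, "WT"), derive_region(truth, "WT")),
        tumor_core=dice_score(derive_region(pred, "TC"), derive_region(truth, "TC")),
    )


def soft_dice_loss(probabilities: np.ndarray, truth: np.ndarray) -> float:
    """Differentiable Dice loss: 1 - 2*sum(p*g) / (sum(p^2) + sum(g^2)).

    Reduces to 1 - DSC when probabilities are binary.  Provided as a reusable
    segmentation objective; both-empty input gives loss 0.
    """
    p = np.asarray(probabilities, dtype=float)
    g = np.asarray(truth, dtype=float)
    if p.shape != g.shape:
        raise GeometryError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    denom = float((p**2).sum() + (g**2).sum())
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * float((p * g).sum()) / denom


def sensitivity(pred: np.ndarray, reference: np.ndarray) -> float:
    """Per-voxel sensitivity (recall) of a binary mask against a reference."""
    pred = np.asarray(pred, bool)
    reference = np.asarray(reference, bool)
    _check_same_geometry(pred, reference)
    n_ref = int(reference.sum())
    if n_ref == 0:
        return 1.0
    return int((pred & reference).sum()) / n_ref
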