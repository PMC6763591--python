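"""Volume and label-map I/O, tumor region derivation, geometry validation.

Inputs follow the BraTS convention: four co-registered scalar modalities
(T1, T1Gd, T2, FLAIR) as 3D NIfTI volumes, and an integer label map with
codes 0 (background), 1 (necrosis / non-enhancing), 2 (edema), 4 (enhancing
tumor).  Axis 2 is the axial (slice) axis.  Derived regions:

=========  =======================================
name       definition
=========  =======================================
edema      label 2
ET         label 4 (enhancing tumor)
necrosis   label 1 (incl. non-enhancing)
WT         whole tumor, labels {1, 2, 4}
TC         tumor core, labels {1, 4}
=========  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

MODALITIES = ("t1", "t1gd", "t2", "flair")
VALID_LABELS = frozenset({0, 1, 2, 4})
REGION_NAMES = ("edema", "ET", "necrosis", "WT", "TC")

_REGION_CODES = {
    "edema": (2,),
    "ET": (4,),
    "necrosis": (1,),
    "WT": (1, 2, 4),
    "TC": (1, 4),
}


class GeometryError(ValueError):
    """Shape or spacing mismatch between volumes that must be co-registered."""


@dataclass(frozen=True)
class MultimodalVolume:
    """Four co-registered 3D intensity volumes with shared geometry."""

    t1: np.ndarray
    t1gd: np.ndarray
    t2: np.ndarray
    flair: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shape = self.t1.shape
        for name in MODALITIES:
            arr = getattr(self, name)
            if arr.ndim != 3:
                raise GeometryError(f"modality {name!r} is {arr.ndim}-D, expected 3-D")
            if arr.shape != shape:
                raise GeometryError(
                    f"modality {name!r} shape {arr.shape} != t1 shape {shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"modality {name!r} contains non-finite voxels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"invalid spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def modality(self, name: str) -> np.ndarray:
        if name not in MODALITIES:
            raise KeyError(f"unknown modality {name!r}; expected one of {MODALITIES}")
        return getattr(self, name)


@dataclass(frozen=True)
class TissueLabelMap:
    """Integer label map with BraTS codes {0, 1, 2, 4} and derived regions."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise GeometryError(f"label map is {self.labels.ndim}-D, expected 3-D")
        codes = set(np.unique(self.labels).tolist())
        bad = codes - VALID_LABELS
        if bad:
            raise ValueError(
                f"unknown label code(s) {sorted(bad)}; valid codes are {sorted(VALID_LABELS)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region(self, name: str) -> np.ndarray:
        return derive_region(self, name)

    def region_volume_mm3(self, name: str) -> float:
        return float(self.region(name).sum()) * float(np.prod(self.spacing))


@dataclass(frozen=True)
class BrainMask:
    """Binary mask of in-brain voxels (denominator for brain-volume ratios)."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if self.mask.ndim != 3:
            raise GeometryError("brain mask must be 3-D")
        if not self.mask.any():
            raise ValueError("brain mask is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing))


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected 3-D data, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def load_volume_set(
    t1: str | Path, t1gd: str | Path, t2: str | Path, flair: str | Path
) -> MultimodalVolume:
    """Load and validate the four co-registered modality volumes."""
    arrays, spacings, affines = [], [], []
    for p in (t1, t1gd, t2, flair):
        a, s, aff = _load_nifti(p)
        arrays.append(a.astype(np.float64))
        spacings.append(s)
        affines.append(aff)
    if len({a.shape for a in arrays}) != 1:
        raise GeometryError(f"modality shapes differ: {[a.shape for a in arrays]}")
    if len({s for s in spacings}) != 1:
        raise GeometryError(f"modality spacings differ: {spacings}")
    return MultimodalVolume(*arrays, spacing=spacings[0], affine=affines[0])


def load_label_map(path: str | Path) -> TissueLabelMap:
    """Load a label map, rejecting any code outside {0, 1, 2, 4}."""
    data, spacing, affine = _load_nifti(path)
    if not np.all(data == np.round(data)):
        raise ValueError(f"{path}: label map is not integer-valued")
    return TissueLabelMap(data.astype(np.int16), spacing=spacing, affine=affine)


def save_volume(array: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array), np.eye(4) if affine is None else affine), str(path))


def derive_region(label_map: TissueLabelMap, name: str) -> np.ndarray:
    """Binary mask for a named tumor region (edema, ET, necrosis, WT, TC)."""
    if name not in _REGION_CODES:
        raise KeyError(f"unknown region {name!r}; expected one of {REGION_NAMES}")
    return np.isin(label_map.labels, _REGION_CODES[name])


def compute_brain_mask(vol: MultimodalVolume) -> BrainMask:
    """Brain support: nonzero T1 voxels, cleaned to the largest connected component.

    BraTS inputs are skull-stripped with zero background, so nonzero T1 support
    is the in-brain region; the largest-component cleanup drops stray speckle.
    """
    support = vol.t1 != 0
    if not support.any():
        raise ValueError("volume has no nonzero T1 voxels; cannot derive brain mask")
    lab, n = ndimage.label(support)
    if n > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        support = lab == int(np.argmax(counts))
    return BrainMask(support, spacing=vol.spacing)
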