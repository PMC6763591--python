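"""Volumetric, area, location/extent, histogram-statistic and histogram-graph features.

All features are computed from the tumor label map (and brain mask) of one
subject.  Voxel counts are converted to mm^3 via the voxel spacing.  Ratios
with an empty denominator are reported as NaN (flagged missing), never as
infinity or silently zero, so the feature schema keeps a fixed length.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from gliomics.io import BrainMask, TissueLabelMap, derive_region

VOLUME_FEATURE_NAMES = (
    "vol_wt",
    "vol_wt_over_brain",
    "vol_edema_over_wt",
    "vol_et_over_wt",
    "vol_necrosis_over_wt",
    "vol_edema_over_brain",
    "vol_et_over_brain",
    "vol_necrosis_over_brain",
    "vol_et_over_edema",
    "vol_necrosis_over_edema",
    "vol_edema_plus_et",
    "vol_edema_over_et_plus_necrosis",
    "vol_necrosis_over_edema_plus_et",
)

AREA_PROPERTY_NAMES = (
    "area",
    "centroid_offset",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "orientation",
    "solidity",
    "extent",
)

HISTOGRAM_GRAPH_BINNINGS = (11, 15, 23)
HISTOGRAM_GRAPH_REGIONS = ("WT", "edema", "ET", "necrosis")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def volume_features(label_map: TissueLabelMap, brain: BrainMask) -> dict[str, float]:
    """The 13 volume features (mm^3 and dimensionless ratios), in schema order."""
    if not brain.mask.any():
        raise ValueError("empty brain mask")
    vox = float(np.prod(label_map.spacing))
    v = {r: float(derive_region(label_map, r).sum()) * vox for r in ("WT", "edema", "ET", "necrosis")}
    vb = brain.voxel_count * vox
    out = {
        "vol_wt": v["WT"],
        "vol_wt_over_brain": _ratio(v["WT"], vb),
        "vol_edema_over_wt": _ratio(v["edema"], v["WT"]),
        "vol_et_over_wt": _ratio(v["ET"], v["WT"]),
        "vol_necrosis_over_wt": _ratio(v["necrosis"], v["WT"]),
        "vol_edema_over_brain": _ratio(v["edema"], vb),
        "vol_et_over_brain": _ratio(v["ET"], vb),
        "vol_necrosis_over_brain": _ratio(v["necrosis"], vb),
        "vol_et_over_edema": _ratio(v["ET"], v["edema"]),
        "vol_necrosis_over_edema": _ratio(v["necrosis"], v["edema"]),
        "vol_edema_plus_et": v["edema"] + v["ET"],
        "vol_edema_over_et_plus_necrosis": _ratio(v["edema"], v["ET"] + v["necrosis"]),
        "vol_necrosis_over_edema_plus_et": _ratio(v["necrosis"], v["edema"] + v["ET"]),
    }
    assert tuple(out) == VOLUME_FEATURE_NAMES
    return out


def area_features(label_map: TissueLabelMap, view: int) -> dict[str, float]:
    """Nine shape properties of the whole-tumor silhouette along one axis.

    The silhouette is the logical-OR projection of WT along ``view``
    (0, 1, or 2); properties come from the largest connected component.
    Centroid is reduced to one scalar: its distance from the image center of
    the projection plane, in mm.  Lengths/areas are scaled by the in-plane
    spacing of the projection.
    """
    if view not in (0, 1, 2):
        raise ValueError(f"view must be 0, 1 or 2, got {view}")
    wt = derive_region(label_map, "WT")
    if not wt.any():
        raise ValueError("empty whole-tumor region")
    proj = wt.any(axis=view)
    in_plane = tuple(s for ax, s in enumerate(label_map.spacing) if ax != view)
    lab = measure.label(proj, connectivity=2)
    props = max(measure.regionprops(lab), key=lambda p: p.area)
    # anisotropic spacing: use the geometric mean for length-like quantities
    lin = float(np.sqrt(in_plane[0] * in_plane[1]))
    center = (np.asarray(proj.shape) - 1) / 2.0
    offset = (np.asarray(props.centroid) - center) * np.asarray(in_plane)
    out = {
        "area": float(props.area) * in_plane[0] * in_plane[1],
        "centroid_offset": float(np.linalg.norm(offset)),
        "perimeter": float(props.perimeter) * lin,
        "major_axis_length": float(props.axis_major_length) * lin,
        "minor_axis_length": float(props.axis_minor_length) * lin,
        "eccentricity": float(props.eccentricity),
        "orientation": float(props.orientation),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
    }
    assert tuple(out) == AREA_PROPERTY_NAMES
    return out


def all_area_features(label_map: TissueLabelMap) -> dict[str, float]:
    """27 features: the 9 properties for each of the three projection views."""
    out: dict[str, float] = {}
    for view, tag in zip((0, 1, 2), ("x", "y", "z")):
        for name, val in area_features(label_map, view).items():
            out[f"{name}_view_{tag}"] = val
    return out


def location_extent_features(label_map: TissueLabelMap, brain: BrainMask) -> dict[str, float]:
    """Per-axis WT centroid offset from the brain centroid, bounding-box
    extent, and coordinate spread (std), all in mm — 9 scalars."""
    wt = derive_region(label_map, "WT")
    if not wt.any():
        raise ValueError("empty whole-tumor region")
    coords = np.argwhere(wt).astype(float)
    brain_centroid = np.argwhere(brain.mask).mean(axis=0)
    spacing = np.asarray(label_map.spacing)
    centroid = coords.mean(axis=0)
    extent = coords.max(axis=0) - coords.min(axis=0) + 1
    spread = coords.std(axis=0)
    out: dict[str, float] = {}
    for ax, tag in enumerate(("x", "y", "z")):
        out[f"centroid_offset_{tag}"] = float((centroid[ax] - brain_centroid[ax]) * spacing[ax])
        out[f"extent_{tag}"] = float(extent[ax] * spacing[ax])
        out[f"spread_{tag}"] = float(spread[ax] * spacing[ax])
    return out


def histogram_stats(values: np.ndarray, n_bins: int = 64) -> dict[str, float]:
    """Mean, variance, skewness, kurtosis of region intensities plus
    histogram energy (sum p^2) and entropy (-sum p log2 p) at ``n_bins`` bins."""
    from gliomics.fractal import map_region_stats

    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("empty region")
    return map_region_stats(v, n_bins=n_bins)


def histogram_graph_features(
    intensities: np.ndarray, region_mask: np.ndarray, prefix: str = ""
) -> dict[str, float]:
    """52 histogram-graph features for one (modality, region) pair.

    Bin frequencies at 11, 15 and 23 bins spanning the region's min-max
    intensity, plus the max-frequency bin index for each binning
    (11 + 15 + 23 + 3 = 52).  An empty region yields 52 NaNs, preserving the
    schema length.
    """
    vals = np.asarray(intensities, float)[np.asarray(region_mask, bool)]
    out: dict[str, float] = {}
    for nb in HISTOGRAM_GRAPH_BINNINGS:
        if vals.size == 0:
            freqs = np.full(nb, np.nan)
            argmax = np.nan
        else:
            lo, hi = vals.min(), vals.max()
            if hi == lo:
                hi = lo + 1.0  # constant region: all mass in bin 0
            freqs, _ = np.histogram(vals, bins=nb, range=(lo, hi))
            argmax = int(np.argmax(freqs))
        for j in range(nb):
            out[f"{prefix}freq_b{nb}_{j}"] = float(freqs[j])
        out[f"{prefix}argmax_b{nb}"] = float(argmax)
    return out


def histogram_graph_block(volume, label_map: TissueLabelMap) -> dict[str, float]:
    """Full 832-feature block: 52 features x 4 modalities x 4 regions."""
    from gliomics.io import MODALITIES

    out: dict[str, float] = {}
    for mod in MODALITIES:
        img = volume.modality(mod)
        for region in HISTOGRAM_GRAPH_REGIONS:
            mask = derive_region(label_map, region)
            out.update(
                histogram_graph_features(img, mask, prefix=f"hg_{mod}_{region}_")
            )
    return out
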