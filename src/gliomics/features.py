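"""Per-subject feature table assembly.

Collects every feature family into one flat, name-keyed mapping per subject:

=========  ==========================================================  =======
prefix     family                                                      count*
=========  ==========================================================  =======
vol_       volume features (mm^3 and ratios)                           13
area_      9 silhouette properties x 3 projection views                27
loc_       per-axis centroid offset / extent / spread                  9
hstat_     6 histogram statistics x 3 tissues x 4 modalities           72
tex_       texture-map statistics, 4 representations x 4 modalities
           x 4 regions x 6 statistics                                  384
txn_       texton occupancy histograms, K bins x 4 modalities
           x 4 regions                                                 256
hg_        histogram-graph features, 52 x 4 modalities x 4 regions     832
euler_     directional Euler vectors, 7200 x 4 regions                 28800
=========  ==========================================================  =======

(*) counts for the default configuration; the texture block is config-driven
and its schema is enumerable via :func:`schema_report`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gliomics import fractal, shape
from gliomics.euler import ect_region_vector
from gliomics.io import MODALITIES, BrainMask, MultimodalVolume, TissueLabelMap, derive_region

REGIONS = ("WT", "edema", "ET", "necrosis")
TISSUES = ("edema", "ET", "necrosis")


@dataclass(frozen=True)
class FeatureConfig:
    representations: tuple[str, ...] = ("raw", "ptpsa", "mbm", "holder")
    texton: bool = True
    texton_k: int = fractal.DEFAULT_TEXTON_K
    texton_seed: int = fractal.DEFAULT_TEXTON_SEED
    window: int = fractal.DEFAULT_WINDOW
    scales: tuple[int, ...] = fractal.DEFAULT_SCALES
    holder_radii: tuple[int, ...] = fractal.DEFAULT_HOLDER_RADII
    histogram_bins: int = 64
    euler: bool = True
    euler_angles: int = 72
    euler_points: int = 100
    bbox_margin: int = 4
    texton_fit_sample: int = 20000


def schema_report(config: FeatureConfig = FeatureConfig()) -> dict[str, int]:
    """Feature counts per family implied by a configuration."""
    n_tex = len(config.representations) * len(MODALITIES) * len(REGIONS) * len(fractal.STATISTICS)
    counts = {
        "volume": len(shape.VOLUME_FEATURE_NAMES),
        "area": len(shape.AREA_PROPERTY_NAMES) * 3,
        "location": 9,
        "histstat": len(fractal.STATISTICS) * len(TISSUES) * len(MODALITIES),
        "texture": n_tex,
        "texton": (config.texton_k * len(MODALITIES) * len(REGIONS)) if config.texton else 0,
        "histgraph": sum(shape.HISTOGRAM_GRAPH_BINNINGS + (1,) * 3) * len(MODALITIES) * len(REGIONS),
        "euler": (config.euler_angles * config.euler_points * len(REGIONS)) if config.euler else 0,
    }
    counts["total"] = sum(counts.values())
    return counts


def _wt_bbox(label_map: TissueLabelMap, margin: int):
    wt = derive_region(label_map, "WT")
    if not wt.any():
        raise ValueError("empty whole-tumor region")
    lo = np.maximum(np.argwhere(wt).min(axis=0) - margin, 0)
    hi = np.minimum(np.argwhere(wt).max(axis=0) + margin + 1, wt.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _texture_map_stack(img: np.ndarray, rep: str, config: FeatureConfig) -> np.ndarray:
    """Slice-wise texture representation of a (cropped) 3D image."""
    if rep == "raw":
        return img
    out = np.empty_like(img, dtype=float)
    for z in range(img.shape[2]):
        sl = img[:, :, z]
        if rep == "ptpsa":
            out[:, :, z] = fractal.ptpsa_map(sl, config.window, config.scales)
        elif rep == "mbm":
            out[:, :, z] = fractal.mbm_hurst_map(sl, config.window, config.scales).values
        elif rep == "holder":
            out[:, :, z] = fractal.holder_map(sl, config.holder_radii)
        else:
            raise ValueError(f"unknown representation {rep!r}")
    return out


def extract_subject_features(
    vol: MultimodalVolume,
    label_map: TissueLabelMap,
    brain: BrainMask,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """All feature families for one subject, as a flat name -> value mapping.

    Windowed texture maps are computed inside the whole-tumor bounding box
    (padded by ``bbox_margin``); all other features use the full volume.
    Empty regions contribute NaN (flagged missing) at fixed schema positions.
    """
    out: dict[str, float] = {}
    out.update(shape.volume_features(label_map, brain))  # names carry vol_ already
    out.update({f"area_{k}": v for k, v in shape.all_area_features(label_map).items()})
    out.update({f"loc_{k}": v for k, v in shape.location_extent_features(label_map, brain).items()})

    region_masks = {r: derive_region(label_map, r) for r in REGIONS}
    for mod in MODALITIES:
        img = vol.modality(mod)
        for tissue in TISSUES:
            mask = region_masks[tissue]
            vals = img[mask] if mask.any() else np.array([])
            stats = fractal.map_region_stats(vals, n_bins=config.histogram_bins)
            out.update({f"hstat_{mod}_{tissue}_{k}": v for k, v in stats.items()})

    bbox = _wt_bbox(label_map, config.bbox_margin)
    crop_masks = {r: m[bbox] for r, m in region_masks.items()}
    for mod in MODALITIES:
        crop = vol.modality(mod)[bbox].astype(float)
        for rep in config.representations:
            tmap = _texture_map_stack(crop, rep, config)
            for region in REGIONS:
                m = crop_masks[region]
                vals = tmap[m] if m.any() else np.array([])
                stats = fractal.map_region_stats(vals, n_bins=config.histogram_bins)
                out.update(
                    {f"tex_{rep}_{mod}_{region}_{k}": v for k, v in stats.items()}
                )
        if config.texton:
            rng = np.random.default_rng(config.texton_seed)
            brain_crop = brain.mask[bbox]
            sample = np.zeros_like(brain_crop)
            idx = np.argwhere(brain_crop)
            if len(idx) > config.texton_fit_sample:
                idx = idx[rng.choice(len(idx), config.texton_fit_sample, replace=False)]
            sample[tuple(idx.T)] = True
            labels, model = fractal.texton_label_map(
                crop, k=config.texton_k, seed=config.texton_seed, sample_mask=sample
            )
            for region in REGIONS:
                hist = fractal.texton_histogram(labels, crop_masks[region], config.texton_k)
                out.update(
                    {f"txn_{mod}_{region}_{j}": float(hist[j]) for j in range(config.texton_k)}
                )

    out.update({f"hg_{k[3:]}" if k.startswith("hg_") else k: v
                for k, v in shape.histogram_graph_block(vol, label_map).items()})

    if config.euler:
        for region in REGIONS:
            vec = ect_region_vector(
                label_map, region, angles=config.euler_angles, points=config.euler_points
            )
            out.update({f"euler_{region}_{j:05d}": float(vec[j]) for j in range(len(vec))})
    return out


def feature_family(name: str) -> str:
    """Family tag of a feature column (prefix before the first underscore)."""
    return name.split("_", 1)[0]


def euler_columns(columns) -> list[str]:
    return [c for c in columns if c.startswith("euler_")]


def build_feature_table(subject_features: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Stack per-subject feature mappings into a subject_id-indexed table."""
    df = pd.DataFrame.from_dict(subject_features, orient="index")
    df.index.name = "subject_id"
    return df
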