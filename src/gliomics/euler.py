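"""Euler characteristic of binary masks and directional Euler-characteristic vectors.

The Euler characteristic chi of a 2D binary mask is computed as V - E + F on
the closed cubical complex of its foreground pixels: each pixel contributes a
face, adjacent pixels share edges, and corner-touching pixels share vertices.
On this complex chi equals (number of 8-connected components) minus (number of
4-connected holes).

The shape descriptor built on top of chi is an Euler-characteristic-transform
style vector: for 72 directions (5 degree steps from the +x image axis) the
directional height h(p) = p . u is thresholded at 100 evenly spaced levels
between the per-slice min and max of h over the region, and entry (k, j) is
chi of the sublevel mask {p : h(p) <= t_j}.  Per-slice matrices are summed
over all axial slices of a region, giving one length-7200 vector per region
(72 angles x 100 filtration points) per subject.
"""

from __future__ import annotations

import numpy as np

from gliomics.io import TissueLabelMap, derive_region

N_ANGLES = 72
N_POINTS = 100


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got {mask.ndim}-D")
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask is not binary; values {vals[:8]}")
        mask = mask.astype(bool)
    return mask


def euler_characteristic_2d(mask: np.ndarray) -> int:
    """chi = V - E + F of the closed cubical complex of foreground pixels.

    Equals components minus holes under 8-connected foreground /
    4-connected background adjacency.
    """
    mask = _check_binary(mask)
    if not mask.any():
        return 0
    p = np.pad(mask, 1)
    faces = int(mask.sum())
    # distinct lattice vertices: any of the 4 touching pixels is foreground
    verts = int((p[:-1, :-1] | p[:-1, 1:] | p[1:, :-1] | p[1:, 1:]).sum())
    # distinct unit edges: either of the two flanking pixels is foreground
    e_h = int((p[:-1, 1:-1] | p[1:, 1:-1]).sum())
    e_v = int((p[1:-1, :-1] | p[1:-1, 1:]).sum())
    return verts - (e_h + e_v) + faces


def _sublevel_counts(height: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """chi at each threshold from a background-inf height image, vectorized.

    A face/edge/vertex of the sublevel complex exists once the minimum height
    over its incident pixels is <= t, so chi(t) reduces to three sorted-array
    rank lookups.
    """
    p = np.pad(height, 1, constant_values=np.inf)
    h_faces = height[np.isfinite(height)]
    h_verts = np.minimum(
        np.minimum(p[:-1, :-1], p[:-1, 1:]), np.minimum(p[1:, :-1], p[1:, 1:])
    )
    h_eh = np.minimum(p[:-1, 1:-1], p[1:, 1:-1])
    h_ev = np.minimum(p[1:-1, :-1], p[1:-1, 1:])
    f = np.sort(h_faces)
    v = np.sort(h_verts[np.isfinite(h_verts)])
    e = np.sort(np.concatenate([h_eh[np.isfinite(h_eh)], h_ev[np.isfinite(h_ev)]]))
    return (
        np.searchsorted(v, thresholds, side="right")
        - np.searchsorted(e, thresholds, side="right")
        + np.searchsorted(f, thresholds, side="right")
    )


def ect_slice(
    mask: np.ndarray, angles: int = N_ANGLES, points: int = N_POINTS
) -> np.ndarray:
    """72x100 integer matrix of sublevel-set Euler characteristics.

    Row k is the direction theta_k = 5k degrees (from the +x image axis,
    counter-clockwise); column j is the j-th of 100 evenly spaced height
    thresholds between the min and max directional height over the mask.
    An empty mask yields the zero matrix.
    """
    mask = _check_binary(mask)
    out = np.zeros((angles, points), dtype=np.int64)
    if not mask.any():
        return out
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop = mask[r0:r1, c0:c1]
    yy, xx = np.mgrid[0 : crop.shape[0], 0 : crop.shape[1]]
    thetas = np.deg2rad(np.arange(angles) * (360.0 / angles))
    for k, th in enumerate(thetas):
        h = xx * np.cos(th) + yy * np.sin(th)
        hf = h[crop]
        lo, hi = hf.min(), hf.max()
        thresholds = np.linspace(lo, hi, points)
        height = np.where(crop, h, np.inf)
        out[k] = _sublevel_counts(height, thresholds)
    return out


def ect_region_vector(
    label_map: TissueLabelMap,
    region: str,
    angles: int = N_ANGLES,
    points: int = N_POINTS,
) -> np.ndarray:
    """Length angles*points vector: per-slice ECT matrices summed over axial slices.

    Flattened angle-major (row k covers the 100 filtration points of direction
    theta_k).  An empty region yields the zero vector.
    """
    mask3d = derive_region(label_map, region)
    total = np.zeros((angles, points), dtype=np.int64)
    for z in range(mask3d.shape[2]):
        sl = mask3d[:, :, z]
        if sl.any():
            total += ect_slice(sl, angles=angles, points=points)
    return total.reshape(-1)
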