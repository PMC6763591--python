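"""Fractal and texture representations of MRI slices.

Four per-pixel texture representations of the intensity surface, all computed
slice-wise on axial slices with reflect padding at the borders:

* **PTPSA** (piecewise triangular prism surface area): the intensity surface
  over each pixel's window is tiled into s x s cells at several scales; each
  cell's four corner intensities plus their mean at the cell center span four
  triangles of a prism whose total area A(s) scales as s^(2-FD).  The fractal
  dimension FD = 2 - slope of log A(s) vs log s lies in [2, 3]; a flat surface
  gives exactly 2.
* **mBm Hurst map**: the local Hurst exponent H of a multifractional Brownian
  surface, from the scaling of mean squared increments E|I(x+s)-I(x)|^2
  ~ s^(2H) inside each pixel's window; clamped to [0, 1].
* **Hoelder map**: the pointwise Hoelder regularity exponent, slope of
  log oscillation (max - min within radius r) vs log r; clamped to [0, 1].
* **Texton labels**: pixels are assigned to K prototype filter-response
  vectors (textons) learned by k-means over responses to a small bank of
  Gaussian, Laplacian-of-Gaussian and oriented-bar filters.

Region-level summaries of these maps feed the texture block of the feature
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.cluster import KMeans

REPRESENTATIONS = ("raw", "ptpsa", "mbm", "holder", "texton")

DEFAULT_WINDOW = 9
DEFAULT_SCALES = (1, 2, 4)
DEFAULT_HOLDER_RADII = (1, 2, 3, 4)
DEFAULT_TEXTON_K = 16
DEFAULT_TEXTON_SEED = 17


@dataclass(frozen=True)
class TextureMap:
    values: np.ndarray
    representation: str
    modality: str
    degenerate: np.ndarray | None = None  # flag map for zero-variance windows


def _check_slice(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D slice, got {img.ndim}-D")
    return img


def _loglog_slope(log_x: np.ndarray, log_y: np.ndarray) -> np.ndarray:
    """Least-squares slope of log_y (stacked along axis 0) vs log_x."""
    lx = log_x - log_x.mean()
    denom = (lx**2).sum()
    ly = log_y - log_y.mean(axis=0)
    return np.tensordot(lx, ly, axes=(0, 0)) / denom


def _triangle_area(p1, p2, p3):
    """Area of 3D triangles given as (..., 3) corner stacks, vectorized."""
    u = p2 - p1
    v = p3 - p1
    cx = u[..., 1] * v[..., 2] - u[..., 2] * v[..., 1]
    cy = u[..., 2] * v[..., 0] - u[..., 0] * v[..., 2]
    cz = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    return 0.5 * np.sqrt(cx**2 + cy**2 + cz**2)


def _prism_cell_areas(img: np.ndarray, s: int) -> np.ndarray:
    """Total triangular-prism surface area of each s x s cell.

    Output[i, j] is the area of the cell whose corners sit at pixels
    (i, j), (i+s, j), (i, j+s), (i+s, j+s); shape (H-s, W-s).
    """
    a = img[:-s, :-s]
    b = img[:-s, s:]
    c = img[s:, :-s]
    d = img[s:, s:]
    e = (a + b + c + d) / 4.0
    h = s / 2.0

    def pt(x, y, z):
        out = np.empty(z.shape + (3,))
        out[..., 0] = x
        out[..., 1] = y
        out[..., 2] = z
        return out

    A = pt(0.0, 0.0, a)
    B = pt(s, 0.0, b)
    C = pt(0.0, s, c)
    D = pt(s, s, d)
    E = pt(h, h, e)
    return (
        _triangle_area(A, B, E)
        + _triangle_area(B, D, E)
        + _triangle_area(D, C, E)
        + _triangle_area(C, A, E)
    )


def ptpsa_map(
    img: np.ndarray,
    window: int = DEFAULT_WINDOW,
    scales: tuple[int, ...] = DEFAULT_SCALES,
) -> np.ndarray:
    """Per-pixel PTPSA fractal-dimension map, clamped to [2, 3]."""
    img = _check_slice(img)
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    if len(scales) < 3:
        raise ValueError("need at least 3 scales")
    side = window - 1
    for s in scales:
        if side % s != 0:
            raise ValueError(f"scale {s} does not divide window-1 = {side}")
    if window > min(img.shape):
        raise ValueError(f"window {window} exceeds slice shape {img.shape}")
    half = window // 2
    pad = np.pad(img, half, mode="reflect")
    H, W = img.shape
    log_area = np.empty((len(scales), H, W))
    for si, s in enumerate(scales):
        cells = _prism_cell_areas(pad, s)  # anchored at padded coords
        # window of pixel (i,j) starts at padded coord (i, j); cell anchors
        # within the window step by s over the (window-1)-wide corner lattice
        total = np.zeros((H, W))
        for du in range(0, side, s):
            for dv in range(0, side, s):
                total += cells[du : du + H, dv : dv + W]
        log_area[si] = np.log(total)
    slope = _loglog_slope(np.log(np.asarray(scales, float)), log_area)
    return np.clip(2.0 - slope, 2.0, 3.0)


def mbm_hurst_map(
    img: np.ndarray,
    window: int = DEFAULT_WINDOW,
    scales: tuple[int, ...] = DEFAULT_SCALES,
) -> TextureMap:
    """Windowed Hurst-exponent map from increment-variance scaling.

    H(x) = slope/2 of log E|increment|^2 vs log s over the pixel's window,
    clamped to [0, 1].  Zero-variance (constant) windows are reported as 1.0
    and flagged in the returned map's ``degenerate`` array.
    """
    img = _check_slice(img)
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    if len(scales) < 2:
        raise ValueError("need at least 2 scales")
    eps = 1e-12
    log_v = np.empty((len(scales),) + img.shape)
    degenerate = np.zeros(img.shape, bool)
    for si, s in enumerate(scales):
        # centered squared increments at lag s, reflect-padded
        p = np.pad(img, s, mode="reflect")
        dx = (p[s:-s, 2 * s :] - p[s:-s, : -2 * s]) ** 2
        dy = (p[2 * s :, s:-s] - p[: -2 * s, s:-s]) ** 2
        v = ndimage.uniform_filter((dx + dy) / 2.0, size=window, mode="reflect")
        degenerate |= v <= eps
        log_v[si] = np.log(np.maximum(v, eps))
    slope = _loglog_slope(np.log(2.0 * np.asarray(scales, float)), log_v)
    hmap = np.clip(slope / 2.0, 0.0, 1.0)
    hmap[degenerate] = 1.0
    return TextureMap(hmap, "mbm", "", degenerate=degenerate)


def holder_map(
    img: np.ndarray, radii: tuple[int, ...] = DEFAULT_HOLDER_RADII
) -> np.ndarray:
    """Pointwise Hoelder exponent: slope of log oscillation vs log radius.

    Oscillation osc_r(x) is max - min intensity within Chebyshev radius r.
    Clamped to [0, 1]; zero-oscillation (locally constant) pixels report 1.0.
    """
    img = _check_slice(img)
    if len(radii) < 3:
        raise ValueError("need at least 3 radii")
    eps = 1e-12
    log_osc = np.empty((len(radii),) + img.shape)
    flat = np.zeros(img.shape, bool)
    for ri, r in enumerate(radii):
        size = 2 * r + 1
        osc = ndimage.maximum_filter(img, size=size, mode="reflect") - ndimage.minimum_filter(
            img, size=size, mode="reflect"
        )
        flat |= osc <= eps
        log_osc[ri] = np.log(np.maximum(osc, eps))
    slope = _loglog_slope(np.log(np.asarray(radii, float)), log_osc)
    out = np.clip(slope, 0.0, 1.0)
    out[flat] = 1.0
    return out


# ---------------------------------------------------------------------------
# texton filter bank


def _gaussian_kernel(sigma: float, size: int) -> np.ndarray:
    ax = np.arange(size) - size // 2
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _log_kernel(sigma: float, size: int) -> np.ndarray:
    ax = np.arange(size) - size // 2
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    k = (r2 - 2 * sigma**2) / sigma**4 * np.exp(-r2 / (2 * sigma**2))
    return k - k.mean()


def _bar_kernel(sigma: float, theta: float, size: int, elongation: float = 3.0) -> np.ndarray:
    """Oriented even bar: anisotropic second Gaussian derivative."""
    ax = np.arange(size) - size // 2
    xx, yy = np.meshgrid(ax, ax)
    xr = xx * np.cos(theta) + yy * np.sin(theta)
    yr = -xx * np.sin(theta) + yy * np.cos(theta)
    sx, sy = sigma, sigma * elongation
    g = np.exp(-(xr**2) / (2 * sx**2) - (yr**2) / (2 * sy**2))
    k = (xr**2 / sx**4 - 1 / sx**2) * g
    return k - k.mean()


def default_filter_bank(size: int = 13) -> list[np.ndarray]:
    """2 Gaussian + 2 LoG + 6 oriented-bar filters at fixed scales."""
    bank = [_gaussian_kernel(s, size) for s in (1.0, 2.0)]
    bank += [_log_kernel(s, size) for s in (1.0, 2.0)]
    bank += [_bar_kernel(1.5, k * np.pi / 6, size) for k in range(6)]
    return bank


@dataclass
class TextonModel:
    centers: np.ndarray  # (K, n_filters)
    bank: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def _filter_responses(volume: np.ndarray, bank: list[np.ndarray]) -> np.ndarray:
    """Slice-wise filter responses; shape (*volume.shape, n_filters).

    Zero-mean (band-pass) filter responses are rectified (absolute value) and
    locally averaged (5x5 energy pooling) so that textons capture local
    texture energy rather than phase — otherwise an oscillating texture
    splits into anti-phase / zero-crossing clusters.
    """
    resp = np.empty(volume.shape + (len(bank),))
    for fi, k in enumerate(bank):
        rectify = abs(k.sum()) < 1e-8
        for z in range(volume.shape[2]):
            r = ndimage.convolve(volume[:, :, z], k, mode="reflect")
            if rectify:
                r = ndimage.uniform_filter(np.abs(r), size=5, mode="reflect")
            resp[:, :, z, fi] = r
    return resp


def texton_label_map(
    volume: np.ndarray,
    bank: list[np.ndarray] | None = None,
    k: int = DEFAULT_TEXTON_K,
    seed: int = DEFAULT_TEXTON_SEED,
    sample_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, TextonModel]:
    """Cluster filter responses into K textons and assign each voxel one.

    Deterministic under ``seed``.  ``sample_mask`` restricts the voxels used
    to fit the k-means centers (assignment still covers the whole volume).
    """
    if bank is None:
        bank = default_filter_bank()
    if not bank:
        raise ValueError("filter bank is empty")
    if k < 2:
        raise ValueError("K must be >= 2")
    vol = np.asarray(volume, float)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    resp = _filter_responses(vol, bank)
    flat = resp.reshape(-1, len(bank))
    fit_on = flat if sample_mask is None else resp[sample_mask]
    if np.unique(fit_on, axis=0).shape[0] < k:
        raise ValueError(f"K={k} exceeds number of distinct response vectors")
    # standardize channels over the fit sample so band-pass (texture) energy
    # is not drowned out by the raw-intensity channels
    mu = fit_on.mean(axis=0)
    sd = fit_on.std(axis=0)
    sd[sd == 0] = 1.0
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    km.fit((fit_on - mu) / sd)
    labels = km.predict((flat - mu) / sd).reshape(vol.shape)
    if np.asarray(volume).ndim == 2:
        labels = labels[:, :, 0]
    return labels, TextonModel(centers=km.cluster_centers_, bank=bank)


def texton_histogram(labels: np.ndarray, region: np.ndarray, k: int) -> np.ndarray:
    """K-bin texton occupancy histogram over a region, normalized to sum 1."""
    vals = labels[region.astype(bool)]
    if vals.size == 0:
        return np.full(k, np.nan)
    h = np.bincount(vals.ravel(), minlength=k).astype(float)
    return h / h.sum()


# ---------------------------------------------------------------------------
# region summary statistics

STATISTICS = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")


def map_region_stats(values: np.ndarray, n_bins: int = 64) -> dict[str, float]:
    """Six summary statistics of a texture map restricted to a region.

    Moments are computed on the raw values; energy and entropy on the
    normalized ``n_bins``-bin histogram.  Degenerate inputs (fewer than two
    values, or zero variance) flag the higher moments as NaN rather than
    reporting silently meaningless numbers.
    """
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        return {s: np.nan for s in STATISTICS}
    out = {"mean": float(v.mean())}
    if v.size < 2 or np.ptp(v) == 0:
        out["variance"] = 0.0 if v.size >= 2 else np.nan
        out["skewness"] = np.nan
        out["kurtosis"] = np.nan
        out["energy"] = 1.0
        out["entropy"] = 0.0
        return out
    out["variance"] = float(v.var())
    out["skewness"] = float(stats.skew(v))
    out["kurtosis"] = float(stats.kurtosis(v))
    p, _ = np.histogram(v, bins=n_bins)
    p = p / p.sum()
    nz = p[p > 0]
    out["energy"] = float((p**2).sum())
    out["entropy"] = float(-(nz * np.log2(nz)).sum())
    return out
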