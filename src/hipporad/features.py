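"""Radiomic feature computation for a masked 3D volume.

Texture matrices (GLCM and run-length) are built per axial slice over
four in-plane directions (0, 45, 90, 135 degrees) and accumulated
across slices, at voxel offsets 1, 4 and 7.  Intensities are first
discretized into ``G`` equal-width gray levels over the ROI min-max
range (default G = 64).  Per-direction texture values are additionally
aggregated across the four directions by arithmetic mean and
population SD ("All Direction" variants).

Features that cannot be computed for a given ROI (e.g. no voxel pair
exists at offset 7 in a thin mask) are emitted as NaN and resolved by
the selection module's mean-imputation step.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from hipporad.catalog import (
    ANGLES,
    HISTOGRAM_PERCENTILES,
    FeatureCatalog,
    default_catalog,
)
from hipporad.io import Mask, Volume

# Unit displacement (row, col) within a slice for each in-plane angle;
# matches the scikit-image graycomatrix convention before symmetrization.
ANGLE_STEPS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}

_LOG2_EPS = 0.0  # probabilities of exactly 0 are excluded from entropy sums


@dataclasses.dataclass
class QuantizedROI:
    """Mask-restricted voxel grid with intensities mapped to 1..G.

    ``levels`` has the bounding-box shape of the mask; out-of-mask
    voxels carry the sentinel 0 and are excluded from all counts.
    """

    levels: np.ndarray
    gray_levels: int
    n_voxels: int


def quantize(volume: Volume, mask: Mask, gray_levels: int = 64) -> QuantizedROI:
    """Discretize in-mask intensities into equal-width bins 1..G.

    A constant ROI maps entirely to level 1.  The returned grid is
    cropped to the mask's bounding box.
    """
    if gray_levels < 2:
        raise ValueError("gray_levels must be >= 2")
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    idx = np.nonzero(m)
    lo = [int(a.min()) for a in idx]
    hi = [int(a.max()) + 1 for a in idx]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = m[box]
    vals = volume.data[box]
    vmin = vals[sub].min()
    vmax = vals[sub].max()
    levels = np.zeros(sub.shape, dtype=np.int32)
    if vmax > vmin:
        scaled = (vals - vmin) / (vmax - vmin) * gray_levels
        lv = np.floor(scaled).astype(np.int32) + 1
        np.clip(lv, 1, gray_levels, out=lv)
    else:
        lv = np.ones(sub.shape, dtype=np.int32)
    levels[sub] = lv[sub]
    return QuantizedROI(levels=levels, gray_levels=gray_levels,
                        n_voxels=int(sub.sum()))


# ---------------------------------------------------------------------------
# first-order (histogram) features
# ---------------------------------------------------------------------------

def _histogram_probs(x: np.ndarray, gray_levels: int) -> np.ndarray:
    vmin, vmax = x.min(), x.max()
    if vmax <= vmin:
        p = np.zeros(gray_levels)
        p[0] = 1.0
        return p
    counts, _ = np.histogram(x, bins=gray_levels, range=(vmin, vmax))
    return counts / counts.sum()


def histogram_features(intensities: np.ndarray, gray_levels: int = 64) -> dict:
    """The catalog's 42 first-order statistics of the ROI intensities.

    Moments use population normalization; skewness and kurtosis of a
    constant ROI are defined as 0; kurtosis is the non-excess
    (Pearson) form; entropy is in bits over the G-bin histogram.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    centered = x - mean
    if sd > 0 and sd**3 > 0 and var**2 > 0:  # guard subnormal underflow
        skew = np.mean(centered**3) / sd**3
        kurt = np.mean(centered**4) / var**2
    else:
        skew = 0.0
        kurt = 0.0
    p = _histogram_probs(x, gray_levels)
    nz = p[p > 0]
    p10, p90 = np.percentile(x, [10, 90])
    mid = x[(x >= p10) & (x <= p90)]
    out = {
        "Mean": mean,
        "Variance": var,
        "Std Deviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Min Intensity": x.min(),
        "Max Intensity": x.max(),
        "Range": x.max() - x.min(),
        "Median": np.median(x),
        "RMS": np.sqrt(np.mean(x**2)),
        "Mean Absolute Deviation": np.mean(np.abs(centered)),
        "Median Absolute Deviation": np.median(np.abs(x - np.median(x))),
        "Robust Mean Absolute Deviation":
            np.mean(np.abs(mid - mid.mean())) if mid.size else 0.0,
        "Interquartile Range": np.percentile(x, 75) - np.percentile(x, 25),
        "Energy": np.sum(x**2),
        "Entropy": -np.sum(nz * np.log2(nz)),
        "Uniformity": np.sum(p**2),
        "Maximum Probability": p.max(),
        "Sum": x.sum(),
        "Quantile0.025": np.percentile(x, 2.5),
        "Quantile0.975": np.percentile(x, 97.5),
    }
    for q in HISTOGRAM_PERCENTILES:
        out[f"Percentile{q}"] = np.percentile(x, q)
    # mode: center of the most populated histogram bin
    vmin, vmax = x.min(), x.max()
    if vmax > vmin:
        width = (vmax - vmin) / gray_levels
        out["Mode"] = vmin + (np.argmax(p) + 0.5) * width
    else:
        out["Mode"] = vmin
    return {k: float(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# form factor (shape) features
# ---------------------------------------------------------------------------

def _boundary_voxels(m: np.ndarray) -> np.ndarray:
    """Indices (k,3) of mask voxels with an exposed face."""
    padded = np.pad(m, 1)
    interior = np.ones_like(m, dtype=bool)
    for ax in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[ax] = slice(0, -2)
        hi[ax] = slice(2, None)
        interior &= padded[tuple(lo)] & padded[tuple(hi)]
    return np.argwhere(m & ~interior)


def _surface_area(m: np.ndarray, spacing) -> float:
    padded = np.pad(m, 1)
    area = 0.0
    face = (spacing[1] * spacing[2], spacing[0] * spacing[2],
            spacing[0] * spacing[1])
    for ax in range(3):
        shifted = np.roll(padded, 1, axis=ax)
        exposed = padded & ~shifted
        # each transition in either direction along ax is one exposed face
        area += 2.0 * exposed.sum() * face[ax] - 0.0
    return float(area)


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 300:
        try:
            from scipy.spatial import ConvexHull
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except Exception:
            pass  # degenerate (coplanar) point sets fall back to brute force
    d2 = 0.0
    for i in range(len(points) - 1):
        diff = points[i + 1:] - points[i]
        d2 = max(d2, float((diff**2).sum(axis=1).max()))
    return np.sqrt(d2)


def shape_features(mask: Mask) -> dict:
    """Nine 3D size/shape descriptors of the binary mask, in mm units.

    Surface area counts exposed voxel faces (not a mesh estimate),
    which makes the values closed-form on toy masks but biases the
    surface-to-volume ratio upward relative to marching-cubes
    estimates.  Maximum 3D Diameter is the largest Euclidean distance
    between centers of boundary voxels.
    """
    m = mask.data.astype(bool)
    spacing = np.asarray(mask.spacing, dtype=float)
    n = int(m.sum())
    vvol = float(np.prod(spacing))
    volume = n * vvol
    surface = _surface_area(m, spacing)
    bnd = _boundary_voxels(m).astype(float) * spacing
    diameter = _max_pairwise_distance(bnd)
    radius = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return {
        "Maximum 3D Diameter": float(diameter),
        "Surface Area": surface,
        "Volume": volume,
        "Surface Volume Ratio": surface / volume,
        "Sphericity": np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / surface,
        "Compactness1": volume / (np.sqrt(np.pi) * surface ** 1.5),
        "Compactness2": 36.0 * np.pi * volume**2 / surface**3,
        "Spherical Disproportion": surface / (4.0 * np.pi * radius**2),
        "Voxel Count": float(n),
    }


# ---------------------------------------------------------------------------
# gray-level co-occurrence matrix
# ---------------------------------------------------------------------------

def glcm(quantized: QuantizedROI, offset: int, angle: int) -> np.ndarray | None:
    """Symmetric normalized GLCM at the given voxel offset and angle.

    Voxel pairs are counted within each axial slice (last axis is the
    slice axis) between in-mask voxels separated by ``offset`` steps
    along ``angle``; counts are accumulated over slices, symmetrized
    and normalized to sum 1.  Returns None when no pair exists.
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    G = quantized.gray_levels
    dr, dc = ANGLE_STEPS[angle]
    dr, dc = dr * offset, dc * offset
    L = quantized.levels
    counts = np.zeros((G, G), dtype=np.float64)
    nr, nc = L.shape[0], L.shape[1]
    # source window such that (r+dr, c+dc) stays in bounds
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    for z in range(L.shape[2]):
        a = L[r0:r1, c0:c1, z]
        b = L[r0 + dr:r1 + dr, c0 + dc:c1 + dc, z]
        ok = (a > 0) & (b > 0)
        if ok.any():
            np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1.0)
    total = counts.sum()
    if total == 0:
        return None
    counts = counts + counts.T
    return counts / counts.sum()


def glcm_features(P: np.ndarray) -> dict:
    """Eight base statistics of a normalized symmetric GLCM.

    Correlation of a degenerate (zero-variance) matrix is 0 by
    convention.  Haralick Correlation is the gray-level covariance
    (the unnormalized numerator of Correlation).
    """
    G = P.shape[0]
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float((i * px).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    nz = P[P > 0]
    cov = float((ii * jj * P).sum()) - mu_x * mu_x
    corr = cov / var_x if var_x > 0 else 0.0
    s = ii + jj - 2.0 * mu_x
    return {
        "GLCMEnergy": float((P**2).sum()),
        "GLCMEntropy": float(-(nz * np.log2(nz)).sum()),
        "Inertia": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": corr,
        "Inverse Difference Moment":
            float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Cluster Shade": float((s**3 * P).sum()),
        "Cluster Prominence": float((s**4 * P).sum()),
        "Haralick Correlation": cov,
    }


# ---------------------------------------------------------------------------
# Haralick sum/difference block (offset 1, direction-averaged)
# ---------------------------------------------------------------------------

def _haralick_from_glcm(P: np.ndarray) -> dict:
    G = P.shape[0]
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}(k), k = 2..2G ; p_{x-y}(k), k = 0..G-1
    psum = np.zeros(2 * G + 1)
    pdiff = np.zeros(G)
    np.add.at(psum, (ii + jj).ravel(), P.ravel())
    np.add.at(pdiff, np.abs(ii - jj).ravel(), P.ravel())
    ks = np.arange(2 * G + 1)
    kd = np.arange(G)
    sa = float((ks * psum).sum())
    da = float((kd * pdiff).sum())
    nzs = psum[psum > 0]
    nzd = pdiff[pdiff > 0]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    nzp = P[P > 0]
    hxy = float(-(nzp * np.log2(nzp)).sum())
    pxpy = np.outer(px, py)
    okm = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[okm] * np.log2(pxpy[okm])).sum())
    ok2 = pxpy > 0
    hxy2 = float(-(pxpy[ok2] * np.log2(pxpy[ok2])).sum())
    nzx = px[px > 0]
    hx = float(-(nzx * np.log2(nzx)).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return {
        "Haralick Sum Average": sa,
        "Haralick Sum Entropy": float(-(nzs * np.log2(nzs)).sum()),
        "Haralick Sum Variance": float(((ks - sa) ** 2 * psum).sum()),
        "Haralick Difference Average": da,
        "Haralick Difference Entropy": float(-(nzd * np.log2(nzd)).sum()),
        "Haralick Difference Variance": float(((kd - da) ** 2 * pdiff).sum()),
        "Haralick Information Measure 1": imc1,
        "Haralick Information Measure 2": imc2,
        "Haralick Autocorrelation": float((ii * jj * P).sum()),
        "Haralick Maximum Probability": float(P.max()),
    }


def haralick_block(quantized: QuantizedROI) -> dict:
    """Ten sum/difference GLCM statistics at offset 1, averaged over
    the four in-plane directions (directions with no voxel pair are
    excluded from the average)."""
    per_dir = []
    for angle in ANGLES:
        P = glcm(quantized, offset=1, angle=angle)
        if P is not None:
            per_dir.append(_haralick_from_glcm(P))
    if not per_dir:
        return {k: np.nan for k in per_dir_keys()}
    return {k: float(np.mean([d[k] for d in per_dir]))
            for k in per_dir[0]}


def per_dir_keys() -> list:
    from hipporad.catalog import HARALICK_FEATURES
    return list(HARALICK_FEATURES)


# ---------------------------------------------------------------------------
# run-length matrix
# ---------------------------------------------------------------------------

def rlm(quantized: QuantizedROI, offset: int, angle: int):
    """Gray-level run-length matrix at a sampling stride.

    Runs are maximal sequences of equal gray level encountered when a
    slice is traversed along ``angle`` visiting every ``offset``-th
    voxel; out-of-mask voxels break runs.  At stride 1 this is the
    classical Galloway run-length matrix.  Returns ``(counts, n_runs)``
    with ``counts`` of shape (G, R); ``counts`` is None when the ROI
    admits no run.
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    G = quantized.gray_levels
    dr, dc = ANGLE_STEPS[angle]
    dr, dc = dr * offset, dc * offset
    L = quantized.levels
    nr, nc, ns = L.shape
    runs: dict[tuple[int, int], int] = {}
    max_len = 0
    for z in range(ns):
        sl = L[:, :, z]
        if not sl.any():
            continue
        for r in range(nr):
            for c in range(nc):
                # line start: the predecessor along (dr,dc) is off-grid
                pr, pc = r - dr, c - dc
                if 0 <= pr < nr and 0 <= pc < nc:
                    continue
                # walk the line at the stride
                cur_level = 0
                cur_len = 0
                rr, cc = r, c
                while 0 <= rr < nr and 0 <= cc < nc:
                    lev = int(sl[rr, cc])
                    if lev == cur_level and lev != 0:
                        cur_len += 1
                    else:
                        if cur_level != 0:
                            key = (cur_level, cur_len)
                            runs[key] = runs.get(key, 0) + 1
                            max_len = max(max_len, cur_len)
                        cur_level = lev
                        cur_len = 1 if lev != 0 else 0
                    rr += dr
                    cc += dc
                if cur_level != 0:
                    key = (cur_level, cur_len)
                    runs[key] = runs.get(key, 0) + 1
                    max_len = max(max_len, cur_len)
    if not runs:
        return None, 0
    counts = np.zeros((G, max_len), dtype=np.float64)
    for (lev, ln), k in runs.items():
        counts[lev - 1, ln - 1] = k
    return counts, int(counts.sum())


def rlm_features(counts: np.ndarray, n_runs: int) -> dict:
    """Ten run-count-normalized RLM statistics."""
    G, R = counts.shape
    i = np.arange(1, G + 1)[:, None].astype(float)
    ell = np.arange(1, R + 1)[None, :].astype(float)
    r = counts
    nr = float(n_runs)
    return {
        "Short Run Emphasis": float((r / ell**2).sum() / nr),
        "Long Run Emphasis": float((r * ell**2).sum() / nr),
        "Gray Level Nonuniformity": float((r.sum(axis=1) ** 2).sum() / nr),
        "Run Length Nonuniformity": float((r.sum(axis=0) ** 2).sum() / nr),
        "Low Gray Level Run Emphasis": float((r / i**2).sum() / nr),
        "High Gray Level Run Emphasis": float((r * i**2).sum() / nr),
        "Short Run Low Gray Level Emphasis":
            float((r / (i**2 * ell**2)).sum() / nr),
        "Short Run High Gray Level Emphasis":
            float((r * i**2 / ell**2).sum() / nr),
        "Long Run Low Gray Level Emphasis":
            float((r * ell**2 / i**2).sum() / nr),
        "Long Run High Gray Level Emphasis":
            float((r * i**2 * ell**2).sum() / nr),
    }


# ---------------------------------------------------------------------------
# direction aggregation and full extraction
# ---------------------------------------------------------------------------

def aggregate_directions(values) -> tuple[float, float]:
    """Mean and population SD over the available per-direction values.

    Missing (None/NaN) directions are excluded; with no direction
    available both aggregates are NaN; a single direction yields
    (value, 0).
    """
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return np.nan, np.nan
    arr = np.asarray(vals, dtype=float)
    return float(arr.mean()), float(arr.std())


def extract_all(volume: Volume, mask: Mask,
                catalog: FeatureCatalog | None = None) -> pd.Series:
    """Compute one value per catalog entry for a volume/mask pair.

    Returns a float Series indexed by catalog feature names, in
    catalog order; non-computable entries are NaN.
    """
    if catalog is None:
        catalog = default_catalog()
    G = catalog.gray_levels
    q = quantize(volume, mask, G)
    roi_vals = volume.data[mask.data.astype(bool)]

    values: dict[str, float] = {}
    values.update(histogram_features(roi_vals, G))
    values.update(shape_features(mask))

    for off in catalog.offsets:
        per_dir: dict[str, list] = {b: [] for b in catalog.config["glcm_base"]}
        for angle in ANGLES:
            P = glcm(q, offset=off, angle=angle)
            feats = glcm_features(P) if P is not None else None
            for base in per_dir:
                v = feats[base] if feats is not None else np.nan
                per_dir[base].append(v)
                values[f"{base}_angle{angle}_offset{off}"] = v
        for base, vals in per_dir.items():
            m, s = aggregate_directions(vals)
            values[f"{base}_All Direction_offset{off}"] = m
            values[f"{base}_All Direction_offset{off}_SD"] = s

    for name, v in haralick_block(q).items():
        values[f"{name}_offset1"] = v

    for off in catalog.offsets:
        per_dir = {b: [] for b in catalog.config["rlm_base"]}
        for angle in ANGLES:
            counts, n_runs = rlm(q, offset=off, angle=angle)
            feats = rlm_features(counts, n_runs) if counts is not None else None
            for base in per_dir:
                v = feats[base] if feats is not None else np.nan
                per_dir[base].append(v)
                values[f"{base}_angle{angle}_offset{off}"] = v
        for base, vals in per_dir.items():
            m, s = aggregate_directions(vals)
            values[f"{base}_All Direction_offset{off}"] = m
            values[f"{base}_All Direction_offset{off}_SD"] = s

    return pd.Series([values[n] for n in catalog.names],
                     index=catalog.names, dtype=float)
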