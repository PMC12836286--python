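"""Gray-level texture matrices (GLCM, GLRLM, GLSZM, NGTDM) in 3D.

All four matrices are computed on the integer gray levels of a
:class:`~noderad.features.quantize.QuantizedRoi` and only consider
voxels inside the mask.

Conventions
-----------
* GLCM and GLRLM use the 13 unique 3D directions at distance 1; each
  direction yields its own matrix, features are computed per direction
  and then averaged (directions producing no pairs/runs are skipped).
* GLCM matrices are symmetrised (each pair counted in both orders) and
  normalised to sum to 1.  Entropy uses log base 2.
* GLRLM runs are maximal same-level streaks along a direction; voxels
  outside the mask break runs.
* GLSZM zones are 26-connected components of equal gray level; the
  matrix is direction-free.
* NGTDM uses the 26-neighbourhood; a voxel contributes only if at least
  one neighbour is inside the mask.  The coarseness denominator is
  guarded at 1e-6.

Degenerate regions (no co-occurring pair in any direction, or no voxel
with an in-mask neighbour) fall back to documented conventions (GLCM
energy 1, all other features 0; NGTDM coarseness = 1/1e-6, rest 0) and
are reported through the module logger.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .quantize import QuantizedRoi

logger = logging.getLogger(__name__)

#: The 13 unique 3D direction vectors (distance 1, up to sign).
DIRECTIONS_13 = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

GLCM_FEATURE_NAMES = (
    "glcm_energy",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_homogeneity",
    "glcm_entropy",
    "glcm_dissimilarity",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
)

GLRLM_FEATURE_NAMES = (
    "glrlm_short_run_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_gray_level_nonuniformity",
    "glrlm_run_length_nonuniformity",
    "glrlm_run_percentage",
    "glrlm_low_gray_run_emphasis",
    "glrlm_high_gray_run_emphasis",
    "glrlm_short_run_low_gray_emphasis",
    "glrlm_short_run_high_gray_emphasis",
    "glrlm_long_run_low_gray_emphasis",
    "glrlm_long_run_high_gray_emphasis",
)

GLSZM_FEATURE_NAMES = (
    "glszm_small_area_emphasis",
    "glszm_large_area_emphasis",
    "glszm_gray_level_nonuniformity",
    "glszm_gray_level_nonuniformity_normalized",
    "glszm_size_zone_nonuniformity",
    "glszm_size_zone_nonuniformity_normalized",
    "glszm_zone_percentage",
    "glszm_gray_level_variance",
    "glszm_zone_variance",
    "glszm_zone_entropy",
    "glszm_low_gray_zone_emphasis",
    "glszm_high_gray_zone_emphasis",
    "glszm_small_area_low_gray_emphasis",
    "glszm_small_area_high_gray_emphasis",
    "glszm_large_area_low_gray_emphasis",
    "glszm_large_area_high_gray_emphasis",
)

NGTDM_FEATURE_NAMES = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)

_COARSENESS_GUARD = 1e-6


def _shift(a: np.ndarray, offset, fill=0) -> np.ndarray:
    """Return array ``out`` with ``out[x] = a[x - offset]`` (fill at borders)."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for size, o in zip(a.shape, offset):
        src.append(slice(max(-o, 0), size - max(o, 0)))
        dst.append(slice(max(o, 0), size - max(-o, 0)))
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(q: QuantizedRoi, direction) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix for one direction.

    Returns an (N_g, N_g) matrix summing to 1, or an all-zero matrix if
    the direction yields no in-mask voxel pair.
    """
    d = tuple(direction)
    ng = q.n_bins
    neigh_mask = _shift(q.mask, tuple(-c for c in d), fill=False)
    valid = q.mask & neigh_mask
    if not valid.any():
        return np.zeros((ng, ng))
    i = q.levels[valid] - 1
    j = _shift(q.levels, tuple(-c for c in d))[valid] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T  # count each pair in both orders
    return counts / counts.sum()


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    lv = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    px = p.sum(axis=1)
    mu = float((lv * px).sum())  # symmetric: mu_i == mu_j
    sigma2 = float(((lv - mu) ** 2 * px).sum())
    energy = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sigma2 > 0:
        correlation = float((((ii - mu) * (jj - mu)) * p).sum() / sigma2)
    else:
        correlation = 0.0
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    dev = ii + jj - 2.0 * mu
    shade = float((dev**3 * p).sum())
    prominence = float((dev**4 * p).sum())
    return {
        "glcm_energy": energy,
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_homogeneity": homogeneity,
        "glcm_entropy": entropy,
        "glcm_dissimilarity": dissimilarity,
        "glcm_cluster_shade": shade,
        "glcm_cluster_prominence": prominence,
    }


def glcm_features(q: QuantizedRoi) -> dict[str, float]:
    """8 co-occurrence features averaged over the 13 directions."""
    per_dir = []
    for d in DIRECTIONS_13:
        p = glcm_matrix(q, d)
        if p.sum() > 0:
            per_dir.append(_glcm_features_one(p))
    if not per_dir:
        logger.warning("GLCM degenerate: no co-occurring pair in any direction")
        out = {name: 0.0 for name in GLCM_FEATURE_NAMES}
        out["glcm_energy"] = 1.0
        return out
    return {
        name: float(np.mean([f[name] for f in per_dir]))
        for name in GLCM_FEATURE_NAMES
    }


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(q: QuantizedRoi, direction) -> np.ndarray:
    """Run-length matrix for one direction.

    Entry (i, l-1) counts maximal in-mask runs of gray level i+1 with
    length l along ``direction``.  Shape is (N_g, max_run_length).
    """
    d = tuple(direction)
    back = d
    fwd = tuple(-c for c in d)
    same_next = (
        q.mask
        & _shift(q.mask, fwd, fill=False)
        & (q.levels == _shift(q.levels, fwd))
    )  # run continues from x to x+d
    # Dynamic program: L[x] = 1 + L[x+d] while the run continues.
    length = np.ones(q.mask.shape, dtype=np.int32)
    length[~q.mask] = 0
    while True:
        nxt = np.where(same_next, 1 + _shift(length, fwd), length)
        nxt[~q.mask] = 0
        if np.array_equal(nxt, length):
            break
        length = nxt
    starts = q.mask & ~_shift(same_next, back, fill=False)
    if not starts.any():  # cannot happen for a nonempty mask
        return np.zeros((q.n_bins, 1))
    run_levels = q.levels[starts] - 1
    run_lengths = length[starts]
    max_len = int(run_lengths.max())
    counts = np.bincount(
        run_levels * max_len + (run_lengths - 1), minlength=q.n_bins * max_len
    )
    return counts.reshape(q.n_bins, max_len).astype(float)


def _glrlm_features_one(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = r.sum()
    lv = np.arange(1, r.shape[0] + 1, dtype=float)[:, None]
    ln = np.arange(1, r.shape[1] + 1, dtype=float)[None, :]
    sre = (r / ln**2).sum() / nr
    lre = (r * ln**2).sum() / nr
    gln = (r.sum(axis=1) ** 2).sum() / nr
    rln = (r.sum(axis=0) ** 2).sum() / nr
    rp = nr / n_voxels
    lgre = (r / lv**2).sum() / nr
    hgre = (r * lv**2).sum() / nr
    srlge = (r / (lv**2 * ln**2)).sum() / nr
    srhge = (r * lv**2 / ln**2).sum() / nr
    lrlge = (r * ln**2 / lv**2).sum() / nr
    lrhge = (r * lv**2 * ln**2).sum() / nr
    vals = (sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge)
    return {k: float(v) for k, v in zip(GLRLM_FEATURE_NAMES, vals)}


def glrlm_features(q: QuantizedRoi) -> dict[str, float]:
    """11 run-length features averaged over the 13 directions."""
    n_voxels = int(q.mask.sum())
    per_dir = []
    for d in DIRECTIONS_13:
        r = glrlm_matrix(q, d)
        if r.sum() > 0:
            per_dir.append(_glrlm_features_one(r, n_voxels))
    return {
        name: float(np.mean([f[name] for f in per_dir]))
        for name in GLRLM_FEATURE_NAMES
    }


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(q: QuantizedRoi) -> np.ndarray:
    """Size-zone matrix: entry (i, s-1) counts 26-connected zones of
    gray level i+1 with s voxels."""
    zones: list[tuple[int, int]] = []
    for level in q.present_levels:
        labeled, n = ndimage.label(q.levels == level, structure=_STRUCT_26)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            zones.extend((int(level), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    m = np.zeros((q.n_bins, max_size))
    for level, size in zones:
        m[level - 1, size - 1] += 1
    return m


def glszm_features(q: QuantizedRoi) -> dict[str, float]:
    """16 size-zone features from the direction-free zone matrix."""
    z = glszm_matrix(q)
    nz = z.sum()
    n_voxels = int(q.mask.sum())
    lv = np.arange(1, z.shape[0] + 1, dtype=float)[:, None]
    sz = np.arange(1, z.shape[1] + 1, dtype=float)[None, :]
    p = z / nz
    mu_g = (lv * p).sum()
    mu_s = (sz * p).sum()
    pn = p[p > 0]
    vals = {
        "glszm_small_area_emphasis": (z / sz**2).sum() / nz,
        "glszm_large_area_emphasis": (z * sz**2).sum() / nz,
        "glszm_gray_level_nonuniformity": (z.sum(axis=1) ** 2).sum() / nz,
        "glszm_gray_level_nonuniformity_normalized": (z.sum(axis=1) ** 2).sum()
        / nz**2,
        "glszm_size_zone_nonuniformity": (z.sum(axis=0) ** 2).sum() / nz,
        "glszm_size_zone_nonuniformity_normalized": (z.sum(axis=0) ** 2).sum()
        / nz**2,
        "glszm_zone_percentage": nz / n_voxels,
        "glszm_gray_level_variance": ((lv - mu_g) ** 2 * p).sum(),
        "glszm_zone_variance": ((sz - mu_s) ** 2 * p).sum(),
        "glszm_zone_entropy": -(pn * np.log2(pn)).sum(),
        "glszm_low_gray_zone_emphasis": (z / lv**2).sum() / nz,
        "glszm_high_gray_zone_emphasis": (z * lv**2).sum() / nz,
        "glszm_small_area_low_gray_emphasis": (z / (lv**2 * sz**2)).sum() / nz,
        "glszm_small_area_high_gray_emphasis": (z * lv**2 / sz**2).sum() / nz,
        "glszm_large_area_low_gray_emphasis": (z * sz**2 / lv**2).sum() / nz,
        "glszm_large_area_high_gray_emphasis": (z * lv**2 * sz**2).sum() / nz,
    }
    return {k: float(v) for k, v in vals.items()}


# ---------------------------------------------------------------------------
# NGTDM

_KERNEL_26 = np.ones((3, 3, 3))
_KERNEL_26[1, 1, 1] = 0


def ngtdm_table(q: QuantizedRoi) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_i and summed absolute differences s_i.

    Only voxels with at least one in-mask 26-neighbour contribute.
    Arrays are indexed by gray level - 1 and have length N_g.
    """
    m = q.mask.astype(float)
    neigh_sum = ndimage.convolve(q.levels * m, _KERNEL_26, mode="constant", cval=0.0)
    neigh_cnt = ndimage.convolve(m, _KERNEL_26, mode="constant", cval=0.0)
    valid = q.mask & (neigh_cnt > 0.5)
    n_i = np.zeros(q.n_bins)
    s_i = np.zeros(q.n_bins)
    if valid.any():
        levels = q.levels[valid]
        diffs = np.abs(levels - neigh_sum[valid] / neigh_cnt[valid])
        n_i = np.bincount(levels - 1, minlength=q.n_bins).astype(float)
        s_i = np.bincount(levels - 1, weights=diffs, minlength=q.n_bins)
    return n_i, s_i


def ngtdm_features(q: QuantizedRoi) -> dict[str, float]:
    """5 neighbourhood gray-tone difference features."""
    n_i, s_i = ngtdm_table(q)
    n_total = n_i.sum()
    if n_total == 0:
        logger.warning("NGTDM degenerate: no voxel with an in-mask neighbour")
        return {
            "ngtdm_coarseness": 1.0 / _COARSENESS_GUARD,
            "ngtdm_contrast": 0.0,
            "ngtdm_busyness": 0.0,
            "ngtdm_complexity": 0.0,
            "ngtdm_strength": 0.0,
        }
    p_i = n_i / n_total
    present = p_i > 0
    ngp = int(present.sum())
    lv = np.arange(1, q.n_bins + 1, dtype=float)

    coarseness = 1.0 / max((p_i * s_i).sum(), _COARSENESS_GUARD)

    if ngp > 1:
        pi = p_i[present]
        li = lv[present]
        si = s_i[present]
        dif = li[:, None] - li[None, :]
        pp = pi[:, None] * pi[None, :]
        contrast = (pp * dif**2).sum() / (ngp * (ngp - 1)) * si.sum() / n_total
        denom_busy = np.abs(li[:, None] * pi[:, None] - li[None, :] * pi[None, :]).sum()
        busyness = (pi * si).sum() / denom_busy if denom_busy > 0 else 0.0
        psum = pi[:, None] + pi[None, :]
        complexity = (
            np.abs(dif) * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]) / psum
        ).sum() / n_total
        s_total = si.sum()
        strength = (psum * dif**2).sum() / s_total if s_total > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": float(coarseness),
        "ngtdm_contrast": float(contrast),
        "ngtdm_busyness": float(busyness),
        "ngtdm_complexity": float(complexity),
        "ngtdm_strength": float(strength),
    }
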