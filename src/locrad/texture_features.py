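"""The fixed 161-item radiomic feature vocabulary.

25 intensity features (18 first-order statistics on raw HU + 7 histogram
features on discretised gray levels) and 136 texture features:

* GLCM  (gray level co-occurrence)          25 features x {averaged, merged}
* GLRLM (gray level run length)             16 features x {averaged, merged}
* GLSZM (gray level size zone)              16 features
* GLDZM (gray level distance zone)          16 features
* NGTDM (neighbourhood gray tone difference) 5 features
* NGLDM (neighbouring gray level dependence) 17 features

Definitions follow the standardisation-initiative conventions: symmetric
co-occurrences over the 13 unique 3D directions at Chebyshev distance 1,
26-connected zones, 26-neighbourhoods, dependence coarseness alpha = 0.
"merged" sums the 13 directional matrices before normalisation; "averaged"
computes features per direction and averages them.  Missing voxels (NaN)
never contribute: pairs touching one are skipped, runs break at one, zones
and neighbourhoods exclude them, and they count as ROI border for distance
maps.

Gray levels are discretised with a fixed bin width anchored at the lower
window edge, so Ng is a constant of the window — not of the observed data —
which keeps features comparable across sub-regions of the same tumor.

Degenerate inputs are legal: a constant region yields a finite vector
(zero-variance skewness/kurtosis defined as 0, zero-marginal-variance GLCM
correlation defined as 1, empty-count ratios 0/0 -> 0, NGTDM coarseness
capped at 1e6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocessing import MIN_VOXELS, MaskedVolume

__all__ = [
    "DiscretizedVolume",
    "discretize",
    "glcm_features",
    "glrlm_features",
    "zone_features",
    "neighbourhood_features",
    "intensity_features",
    "extract_feature_vector",
    "feature_names",
    "SmallRegionError",
    "DEFAULT_BIN_WIDTH",
]

DEFAULT_BIN_WIDTH = 5.0

#: cap used for NGTDM coarseness when its denominator vanishes
COARSENESS_CAP = 1e6

#: the 13 unique 3D directions at Chebyshev distance 1 (one per +/- pair)
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS) == 13

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class SmallRegionError(ValueError):
    """Region below the analysable-voxel minimum: excluded, not failed."""


@dataclass(frozen=True)
class DiscretizedVolume:
    """Gray levels 1..ng (0 marks missing) on the analysis grid."""

    levels: np.ndarray  # int array, 0 = missing
    ng: int
    bin_width: float

    @property
    def valid(self) -> np.ndarray:
        return self.levels > 0


def discretize(mv: MaskedVolume, bin_width: float = DEFAULT_BIN_WIDTH) -> DiscretizedVolume:
    """Fixed-bin-width discretisation anchored at the window's lower edge.

    level(x) = floor((x - low) / bin_width) + 1, clamped to [1, Ng] with
    Ng = ceil((high - low + 1) / bin_width) computed from the window alone.
    """
    if not (bin_width > 0):
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    low, high = mv.window
    ng = int(math.ceil((high - low + 1) / bin_width))
    levels = np.zeros(mv.shape, dtype=np.int64)
    valid = mv.valid
    lv = np.floor((mv.data[valid] - low) / bin_width).astype(np.int64) + 1
    levels[valid] = np.clip(lv, 1, ng)
    return DiscretizedVolume(levels=levels, ng=ng, bin_width=float(bin_width))


def _crop_to_valid(levels: np.ndarray) -> np.ndarray:
    """Crop to the bounding box of non-missing voxels (features are
    translation invariant, and small matrices are cheaper)."""
    idx = np.nonzero(levels > 0)
    if idx[0].size == 0:
        raise ValueError("no non-missing voxel in region")
    slices = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    return levels[slices]


# ---------------------------------------------------------------------------
# GLCM


def _glcm_counts(levels: np.ndarray, ng: int, d: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts of non-missing pairs along ``d``."""
    sl_a, sl_b = [], []
    for n, step in zip(levels.shape, d):
        if step == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        elif step == -1:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
        else:
            sl_a.append(slice(0, n))
            sl_b.append(slice(0, n))
    a = levels[tuple(sl_a)].ravel()
    b = levels[tuple(sl_b)].ravel()
    keep = (a > 0) & (b > 0)
    a, b = a[keep] - 1, b[keep] - 1
    mat = np.zeros((ng, ng), dtype=float)
    np.add.at(mat, (a, b), 1.0)
    np.add.at(mat, (b, a), 1.0)
    return mat


def _glcm_from_counts(counts: np.ndarray) -> dict[str, float]:
    n = counts.sum()
    p = counts / n
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((ii * p).sum())
    var = float(((ii - mu) ** 2 * p).sum())

    # diagonal (difference) and cross-diagonal (sum) probabilities
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())
    hxy = ent(p)
    hx = ent(px)
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-(pxpy * log_pxpy).sum())

    off = np.abs(ii - jj) > 0
    out = {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "difference_entropy": ent(p_diff),
        "sum_average": sa,
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "sum_entropy": ent(p_sum),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_normalized": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference_moment_normalized": float(
            (p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()
        ),
        "inverse_variance": float((p[off] / (ii - jj)[off] ** 2).sum()),
        "correlation": (
            float(((ii - mu) * (jj - mu) * p).sum() / var) if var > 0 else 1.0
        ),
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "information_correlation_1": ((hxy - hxy1) / hx) if hx > 0 else 0.0,
        "information_correlation_2": float(
            math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
        ),
    }
    return out


GLCM_FEATURES = tuple(_glcm_from_counts(np.ones((2, 2))).keys())


def glcm_features(disc: DiscretizedVolume, aggregation: str) -> dict[str, float]:
    """25 co-occurrence features, Chebyshev distance 1, 13 directions."""
    if aggregation not in ("averaged", "merged"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    levels = _crop_to_valid(disc.levels)
    mats = [_glcm_counts(levels, disc.ng, d) for d in DIRECTIONS]
    mats = [m for m in mats if m.sum() > 0]
    if not mats:
        raise ValueError("no valid co-occurrence pair in any direction")
    if aggregation == "merged":
        return _glcm_from_counts(sum(mats))
    per_dir = [_glcm_from_counts(m) for m in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM


def _rlm_matrix(levels: np.ndarray, ng: int, d) -> np.ndarray:
    """Run-length matrix along direction ``d``.

    Voxels are ordered along each lattice line parallel to ``d`` (line
    identity = voxel position minus its parameter times ``d``); maximal
    constant runs of non-missing voxels are then found from level changes in
    that ordering.  A missing voxel (level 0) breaks a run.
    """
    idx = np.indices(levels.shape)
    axis = next(i for i in range(3) if d[i] != 0)
    t = idx[axis] * d[axis]  # parameter increasing along +d
    anchors = [(idx[i] - t * d[i]).ravel() for i in range(3)]
    t = t.ravel()
    order = np.lexsort((t, anchors[2], anchors[1], anchors[0]))
    lv = levels.ravel()[order]
    a0, a1, a2 = (a[order] for a in anchors)
    new_run = np.ones(lv.size, dtype=bool)
    new_run[1:] = (
        (a0[1:] != a0[:-1]) | (a1[1:] != a1[:-1]) | (a2[1:] != a2[:-1])
        | (lv[1:] != lv[:-1])
    )
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, lv.size))
    run_levels = lv[starts]
    keep = run_levels > 0
    if not keep.any():
        return np.zeros((ng, 1), dtype=float)
    mat = np.zeros((ng, int(lengths[keep].max())), dtype=float)
    np.add.at(mat, (run_levels[keep] - 1, lengths[keep] - 1), 1.0)
    return mat


def _pad_to_common_width(mats: list[np.ndarray]) -> list[np.ndarray]:
    width = max(m.shape[1] for m in mats)
    return [
        np.pad(m, ((0, 0), (0, width - m.shape[1]))) if m.shape[1] < width else m
        for m in mats
    ]


def _length_matrix_features(mat: np.ndarray, nv: int, prefix_i: str, prefix_j: str) -> dict:
    """Shared feature set for run-length-style matrices m[level, length].

    Used by GLRLM (length = run length), GLSZM (zone size), GLDZM (zone
    distance) and NGLDM (dependence count): same sixteen functional forms on
    the (gray level, count) matrix with the family's own naming.
    """
    ns = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)
    j = np.arange(1, mat.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    ri = mat.sum(axis=1)
    rj = mat.sum(axis=0)
    p = mat / ns
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    pj_pos = p[p > 0]
    return {
        f"short_{prefix_j}_emphasis": float((mat / jj**2).sum() / ns),
        f"long_{prefix_j}_emphasis": float((mat * jj**2).sum() / ns),
        f"low_{prefix_i}_emphasis": float((ri / i**2).sum() / ns),
        f"high_{prefix_i}_emphasis": float((ri * i**2).sum() / ns),
        f"short_{prefix_j}_low_{prefix_i}_emphasis": float((mat / (ii**2 * jj**2)).sum() / ns),
        f"short_{prefix_j}_high_{prefix_i}_emphasis": float((mat * ii**2 / jj**2).sum() / ns),
        f"long_{prefix_j}_low_{prefix_i}_emphasis": float((mat * jj**2 / ii**2).sum() / ns),
        f"long_{prefix_j}_high_{prefix_i}_emphasis": float((mat * ii**2 * jj**2).sum() / ns),
        "gray_level_nonuniformity": float((ri**2).sum() / ns),
        "gray_level_nonuniformity_normalized": float((ri**2).sum() / ns**2),
        f"{prefix_j}_nonuniformity": float((rj**2).sum() / ns),
        f"{prefix_j}_nonuniformity_normalized": float((rj**2).sum() / ns**2),
        "percentage": float(ns / nv),
        "gray_level_variance": float(((ii - mu_i) ** 2 * p).sum()),
        f"{prefix_j}_variance": float(((jj - mu_j) ** 2 * p).sum()),
        "entropy": float(-(pj_pos * np.log2(pj_pos)).sum()),
    }


def _rename(d: dict, mapping: dict) -> dict:
    return {mapping.get(k, k): v for k, v in d.items()}


_GLRLM_RENAME = {
    "short_run_length_emphasis": "short_run_emphasis",
    "long_run_length_emphasis": "long_run_emphasis",
    "low_gray_level_emphasis": "low_gray_level_run_emphasis",
    "high_gray_level_emphasis": "high_gray_level_run_emphasis",
    "short_run_length_low_gray_level_emphasis": "short_run_low_gray_level_emphasis",
    "short_run_length_high_gray_level_emphasis": "short_run_high_gray_level_emphasis",
    "long_run_length_low_gray_level_emphasis": "long_run_low_gray_level_emphasis",
    "long_run_length_high_gray_level_emphasis": "long_run_high_gray_level_emphasis",
    "percentage": "run_percentage",
    "entropy": "run_entropy",
}


def _glrlm_from_matrix(mat: np.ndarray, nv: int) -> dict[str, float]:
    return _rename(_length_matrix_features(mat, nv, "gray_level", "run_length"), _GLRLM_RENAME)


GLRLM_FEATURES = tuple(_glrlm_from_matrix(np.ones((2, 2)), 4).keys())


def glrlm_features(disc: DiscretizedVolume, aggregation: str) -> dict[str, float]:
    """16 run-length features over the 13 directions.

    For the merged variant the run-percentage denominator is the voxel count
    times the number of directions, so that the fraction of realised runs
    stays in (0, 1].
    """
    if aggregation not in ("averaged", "merged"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    levels = _crop_to_valid(disc.levels)
    nv = int((levels > 0).sum())
    mats = _pad_to_common_width([_rlm_matrix(levels, disc.ng, d) for d in DIRECTIONS])
    if aggregation == "merged":
        return _glrlm_from_matrix(sum(mats), nv * len(DIRECTIONS))
    per_dir = [_glrlm_from_matrix(m, nv) for m in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM / GLDZM


def _zones(levels: np.ndarray):
    """Yield (level, zone voxel index arrays) for 26-connected equal-level zones."""
    for lv in np.unique(levels[levels > 0]):
        lab, n = ndimage.label(levels == lv, structure=_CONN26)
        for z in range(1, n + 1):
            yield int(lv), np.nonzero(lab == z)


def _distance_map(valid: np.ndarray) -> np.ndarray:
    """Chebyshev distance to the ROI border; border voxels have distance 1.

    Missing voxels and the volume edge both count as border, so the map is
    computed on the zero-padded valid mask.
    """
    padded = np.pad(valid, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="chessboard")
    return dist[1:-1, 1:-1, 1:-1]


_GLSZM_RENAME = {
    "short_zone_size_emphasis": "small_zone_emphasis",
    "long_zone_size_emphasis": "large_zone_emphasis",
    "low_gray_level_emphasis": "low_gray_level_zone_emphasis",
    "high_gray_level_emphasis": "high_gray_level_zone_emphasis",
    "short_zone_size_low_gray_level_emphasis": "small_zone_low_gray_level_emphasis",
    "short_zone_size_high_gray_level_emphasis": "small_zone_high_gray_level_emphasis",
    "long_zone_size_low_gray_level_emphasis": "large_zone_low_gray_level_emphasis",
    "long_zone_size_high_gray_level_emphasis": "large_zone_high_gray_level_emphasis",
    "percentage": "zone_percentage",
    "entropy": "zone_size_entropy",
}

_GLDZM_RENAME = {
    "short_zone_distance_emphasis": "small_distance_emphasis",
    "long_zone_distance_emphasis": "large_distance_emphasis",
    "low_gray_level_emphasis": "low_gray_level_zone_emphasis",
    "high_gray_level_emphasis": "high_gray_level_zone_emphasis",
    "short_zone_distance_low_gray_level_emphasis": "small_distance_low_gray_level_emphasis",
    "short_zone_distance_high_gray_level_emphasis": "small_distance_high_gray_level_emphasis",
    "long_zone_distance_low_gray_level_emphasis": "large_distance_low_gray_level_emphasis",
    "long_zone_distance_high_gray_level_emphasis": "large_distance_high_gray_level_emphasis",
    "percentage": "zone_percentage",
    "entropy": "zone_distance_entropy",
}


def zone_features(disc: DiscretizedVolume) -> tuple[dict[str, float], dict[str, float]]:
    """(GLSZM, GLDZM): 16 size-zone + 16 distance-zone features.

    Zones are 26-connected components of equal gray level.  The GLDZM
    distance of a zone is the minimum over its voxels of the Chebyshev
    distance to the ROI border (minimum 1).
    """
    levels = _crop_to_valid(disc.levels)
    nv = int((levels > 0).sum())
    dist = _distance_map(levels > 0)
    zones = list(_zones(levels))
    max_size = max(idx[0].size for _, idx in zones)
    max_dist = int(max(dist[idx].min() for _, idx in zones))
    szm = np.zeros((disc.ng, max_size), dtype=float)
    dzm = np.zeros((disc.ng, max_dist), dtype=float)
    for lv, idx in zones:
        szm[lv - 1, idx[0].size - 1] += 1
        dzm[lv - 1, int(dist[idx].min()) - 1] += 1
    glszm = _rename(_length_matrix_features(szm, nv, "gray_level", "zone_size"), _GLSZM_RENAME)
    gldzm = _rename(_length_matrix_features(dzm, nv, "gray_level", "zone_distance"), _GLDZM_RENAME)
    return glszm, gldzm


GLSZM_FEATURES = tuple(_GLSZM_RENAME.get(k, k) for k in
                       _length_matrix_features(np.ones((2, 2)), 4, "gray_level", "zone_size"))
GLDZM_FEATURES = tuple(_GLDZM_RENAME.get(k, k) for k in
                       _length_matrix_features(np.ones((2, 2)), 4, "gray_level", "zone_distance"))


# ---------------------------------------------------------------------------
# NGTDM / NGLDM


def _neighbour_stats(levels: np.ndarray):
    """Per-voxel neighbour sums/counts over the 26-neighbourhood (valid only)."""
    valid = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.convolve((levels * valid).astype(float), kernel, mode="constant")
    nbr_cnt = ndimage.convolve(valid.astype(float), kernel, mode="constant")
    return valid, nbr_sum, nbr_cnt


def ngtdm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """5 neighbourhood gray tone difference features (coarseness, contrast,
    busyness, complexity, strength), 26-neighbourhood, distance 1."""
    levels = _crop_to_valid(disc.levels)
    valid, nbr_sum, nbr_cnt = _neighbour_stats(levels)
    use = valid & (nbr_cnt > 0)
    if not use.any():
        raise ValueError("no voxel with a non-missing neighbour")
    lv = levels[use].astype(float)
    mean_nbr = nbr_sum[use] / nbr_cnt[use]
    ng = disc.ng
    n_i = np.bincount(levels[use].astype(int), minlength=ng + 1)[1:].astype(float)
    s_i = np.zeros(ng)
    np.add.at(s_i, levels[use] - 1, np.abs(lv - mean_nbr))
    nv = float(use.sum())
    p_i = n_i / nv
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1, dtype=float)

    denom_coarse = float((p_i * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_CAP
    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        ii_, jj_ = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float(
            (pi_ * pj_ * (ii_ - jj_) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nv
        )
        denom_busy = float(np.abs(ii_ * pi_ - jj_ * pj_).sum())
        busyness = denom_coarse / denom_busy if denom_busy > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = float(
            (np.abs(ii_ - jj_) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum() / nv
        )
        strength_num = float(((pi_ + pj_) * (ii_ - jj_) ** 2).sum())
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": min(coarseness, COARSENESS_CAP),
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


_NGLDM_RENAME = {
    "short_dependence_count_emphasis": "low_dependence_emphasis",
    "long_dependence_count_emphasis": "high_dependence_emphasis",
    "low_gray_level_emphasis": "low_gray_level_count_emphasis",
    "high_gray_level_emphasis": "high_gray_level_count_emphasis",
    "short_dependence_count_low_gray_level_emphasis": "low_dependence_low_gray_level_emphasis",
    "short_dependence_count_high_gray_level_emphasis": "low_dependence_high_gray_level_emphasis",
    "long_dependence_count_low_gray_level_emphasis": "high_dependence_low_gray_level_emphasis",
    "long_dependence_count_high_gray_level_emphasis": "high_dependence_high_gray_level_emphasis",
    "percentage": "dependence_count_percentage",
    "entropy": "dependence_count_entropy",
}


def ngldm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """17 neighbouring gray level dependence features (alpha = 0).

    The dependence count of a voxel is its number of 26-neighbours with the
    same gray level; matrix column j corresponds to dependence count j - 1.
    """
    levels = _crop_to_valid(disc.levels)
    valid = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS:
        sl_a, sl_b = [], []
        for n, step in zip(levels.shape, d):
            if step == 1:
                sl_a.append(slice(0, n - 1)), sl_b.append(slice(1, n))
            elif step == -1:
                sl_a.append(slice(1, n)), sl_b.append(slice(0, n - 1))
            else:
                sl_a.append(slice(0, n)), sl_b.append(slice(0, n))
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        same = (levels[sl_a] == levels[sl_b]) & (levels[sl_a] > 0)
        dep[sl_a] += same
        dep[sl_b] += same
    nv = int(valid.sum())
    max_dep = int(dep[valid].max())
    mat = np.zeros((disc.ng, max_dep + 1), dtype=float)
    np.add.at(mat, (levels[valid] - 1, dep[valid]), 1.0)
    feats = _length_matrix_features(mat, nv, "gray_level", "dependence_count")
    feats = _rename(feats, _NGLDM_RENAME)
    p = mat / mat.sum()
    feats["dependence_count_energy"] = float((p**2).sum())
    return feats


NGLDM_FEATURES = tuple(_NGLDM_RENAME.get(k, k) for k in
                       _length_matrix_features(np.ones((2, 2)), 4, "gray_level", "dependence_count")
                       ) + ("dependence_count_energy",)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")


def neighbourhood_features(disc: DiscretizedVolume) -> tuple[dict[str, float], dict[str, float]]:
    """(NGTDM, NGLDM) feature dictionaries."""
    return ngtdm_features(disc), ngldm_features(disc)


# ---------------------------------------------------------------------------
# Intensity (first-order) and histogram features


STAT_FEATURES = (
    "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10",
    "p90", "maximum", "iqr", "range", "mad", "rmad", "medad", "cov", "qcod",
    "energy", "rms",
)

HIST_FEATURES = ("mean", "variance", "median", "range", "entropy", "uniformity", "mode")


def intensity_features(mv: MaskedVolume, disc: DiscretizedVolume) -> dict[str, float]:
    """18 first-order statistics on raw HU + 7 histogram features on levels.

    Moments are population moments; kurtosis is excess kurtosis; percentiles
    interpolate linearly between order statistics.  Zero-variance skewness
    and kurtosis are defined as 0, and ratio features guard 0/0 -> 0.  The
    histogram mode is the lowest level among the most frequent ones.
    """
    x = mv.data[mv.valid].astype(float)
    if x.size == 0:
        raise ValueError("no non-missing voxel in region")
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = math.sqrt(var)
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    med = float(np.median(x))
    core = x[(x >= p10) & (x <= p90)]
    out = {
        "stat_mean": mean,
        "stat_variance": var,
        "stat_skewness": float(((x - mean) ** 3).mean() / sd**3) if sd > 0 else 0.0,
        "stat_kurtosis": float(((x - mean) ** 4).mean() / sd**4 - 3.0) if sd > 0 else 0.0,
        "stat_median": med,
        "stat_minimum": float(x.min()),
        "stat_p10": p10,
        "stat_p90": p90,
        "stat_maximum": float(x.max()),
        "stat_iqr": p75 - p25,
        "stat_range": float(x.max() - x.min()),
        "stat_mad": float(np.abs(x - mean).mean()),
        "stat_rmad": float(np.abs(core - core.mean()).mean()) if core.size else 0.0,
        "stat_medad": float(np.abs(x - med).mean()),
        "stat_cov": (sd / mean) if mean != 0 else 0.0,
        "stat_qcod": ((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0,
        "stat_energy": float((x**2).sum()),
        "stat_rms": float(math.sqrt((x**2).mean())),
    }
    lv = disc.levels[disc.valid].astype(float)
    counts = np.bincount(lv.astype(int), minlength=disc.ng + 1)[1:]
    p = counts / counts.sum()
    ppos = p[p > 0]
    out.update({
        "hist_mean": float(lv.mean()),
        "hist_variance": float(lv.var()),
        "hist_median": float(np.median(lv)),
        "hist_range": float(lv.max() - lv.min()),
        "hist_entropy": float(-(ppos * np.log2(ppos)).sum()),
        "hist_uniformity": float((p**2).sum()),
        "hist_mode": float(np.argmax(counts) + 1),
    })
    return out


# ---------------------------------------------------------------------------
# Full vector


def feature_names() -> list[str]:
    """The canonical 161-name vocabulary, in serialisation order."""
    names = [f"stat_{n}" for n in STAT_FEATURES] + [f"hist_{n}" for n in HIST_FEATURES]
    for agg in ("averaged", "merged"):
        names += [f"glcm_{agg}_{n}" for n in GLCM_FEATURES]
    for agg in ("averaged", "merged"):
        names += [f"glrlm_{agg}_{n}" for n in GLRLM_FEATURES]
    names += [f"glszm_{n}" for n in GLSZM_FEATURES]
    names += [f"gldzm_{n}" for n in GLDZM_FEATURES]
    names += [f"ngtdm_{n}" for n in NGTDM_FEATURES]
    names += [f"ngldm_{n}" for n in NGLDM_FEATURES]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())
assert len(FEATURE_NAMES) == 161, len(FEATURE_NAMES)
N_INTENSITY = 25
N_TEXTURE = 136


def extract_feature_vector(
    mv: MaskedVolume,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_voxels: int = MIN_VOXELS,
) -> dict[str, float]:
    """All 161 features of a masked region, as an ordered name -> value dict.

    Raises :class:`SmallRegionError` when the region has fewer than
    ``min_voxels`` analysable voxels — the region is excluded, the call site
    decides how to log it.
    """
    n = mv.roi_voxel_count
    if n < min_voxels:
        raise SmallRegionError(f"region has {n} voxels < minimum {min_voxels}")
    disc = discretize(mv, bin_width)
    out: dict[str, float] = dict(intensity_features(mv, disc))
    for agg in ("averaged", "merged"):
        out.update({f"glcm_{agg}_{k}": v for k, v in glcm_features(disc, agg).items()})
    for agg in ("averaged", "merged"):
        out.update({f"glrlm_{agg}_{k}": v for k, v in glrlm_features(disc, agg).items()})
    szm, dzm = zone_features(disc)
    out.update({f"glszm_{k}": v for k, v in szm.items()})
    out.update({f"gldzm_{k}": v for k, v in dzm.items()})
    ngt, ngl = neighbourhood_features(disc)
    out.update({f"ngtdm_{k}": v for k, v in ngt.items()})
    out.update({f"ngldm_{k}": v for k, v in ngl.items()})
    return {name: out[name] for name in FEATURE_NAMES}
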