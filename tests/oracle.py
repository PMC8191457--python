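"""Independent brute-force oracle for the texture feature vocabulary.

Everything here is deliberately naive — triple loops over voxels, explicit
run walking, BFS zones, loop-based matrix formulas — and shares no code
with the package implementation.  Used to cross-check matrices and all 161
features on small volumes.
"""

from __future__ import annotations

import math

import numpy as np

DIRS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
ALL_NEIGHBOURS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def discretize(data, window_low, window_high, bin_width):
    ng = int(math.ceil((window_high - window_low + 1) / bin_width))
    levels = np.zeros(data.shape, dtype=int)
    nx, ny, nz = data.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                v = data[x, y, z]
                if not np.isnan(v):
                    lv = int(math.floor((v - window_low) / bin_width)) + 1
                    levels[x, y, z] = min(max(lv, 1), ng)
    return levels, ng


def _inside(shape, p):
    return all(0 <= p[i] < shape[i] for i in range(3))


# ---------------------------------------------------------------------------
# matrices


def glcm_counts(levels, ng, d):
    C = np.zeros((ng, ng))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a <= 0:
                    continue
                q = (x + d[0], y + d[1], z + d[2])
                if _inside(levels.shape, q):
                    b = levels[q]
                    if b > 0:
                        C[a - 1, b - 1] += 1
                        C[b - 1, a - 1] += 1
    return C


def rlm_matrix(levels, ng, d, width):
    mat = np.zeros((ng, width))
    shape = levels.shape
    nx, ny, nz = shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                prev = (x - d[0], y - d[1], z - d[2])
                if _inside(shape, prev):
                    continue  # not a line start
                pos = (x, y, z)
                run_level, run_len = 0, 0
                while _inside(shape, pos):
                    lv = levels[pos]
                    if lv > 0 and lv == run_level:
                        run_len += 1
                    else:
                        if run_level > 0:
                            mat[run_level - 1, run_len - 1] += 1
                        run_level, run_len = lv, (1 if lv > 0 else 0)
                    pos = (pos[0] + d[0], pos[1] + d[1], pos[2] + d[2])
                if run_level > 0:
                    mat[run_level - 1, run_len - 1] += 1
    return mat


def zones(levels):
    """26-connected equal-level zones: list of (level, size, min border distance)."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    out = []
    nx, ny, nz = shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if levels[x, y, z] <= 0 or visited[x, y, z]:
                    continue
                lv = levels[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                members = []
                while stack:
                    p = stack.pop()
                    members.append(p)
                    for d in ALL_NEIGHBOURS:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _inside(shape, q) and not visited[q] and levels[q] == lv:
                            visited[q] = True
                            stack.append(q)
                dist = min(border_distance(levels, p) for p in members)
                out.append((int(lv), len(members), dist))
    return out


def border_distance(levels, p):
    """Chebyshev distance of voxel p to the ROI border (edge or missing)."""
    shape = levels.shape
    x, y, z = p
    edge = min(x + 1, shape[0] - x, y + 1, shape[1] - y, z + 1, shape[2] - z)
    best = edge
    nx, ny, nz = shape
    for mx in range(nx):
        for my in range(ny):
            for mz in range(nz):
                if levels[mx, my, mz] <= 0:
                    d = max(abs(x - mx), abs(y - my), abs(z - mz))
                    best = min(best, d)
    return best


def ngtdm_components(levels, ng):
    """(n_i, s_i, nv) over voxels with at least one valid neighbour."""
    shape = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    nv = 0
    nx, ny, nz = shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a <= 0:
                    continue
                vals = []
                for d in ALL_NEIGHBOURS:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and levels[q] > 0:
                        vals.append(levels[q])
                if not vals:
                    continue
                nv += 1
                n[a - 1] += 1
                s[a - 1] += abs(a - sum(vals) / len(vals))
    return n, s, nv


def ngldm_matrix(levels, ng):
    """Dependence-count matrix s[i, k], k = number of equal-level neighbours."""
    shape = levels.shape
    mat = np.zeros((ng, 27))
    nx, ny, nz = shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a <= 0:
                    continue
                k = 0
                for d in ALL_NEIGHBOURS:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and levels[q] == a:
                        k += 1
                mat[a - 1, k] += 1
    return mat


# ---------------------------------------------------------------------------
# features from matrices (loop-based)


def glcm_feats(C):
    N = C.sum()
    ng = C.shape[0]
    p = C / N
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    pd = [0.0] * ng
    ps = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pd[abs(i - j)] += p[i, j]
            ps[i + j] += p[i, j]
    da = sum(k * pd[k] for k in range(ng))
    sa = sum((k + 2) * ps[k] for k in range(len(ps)))

    def H(q):
        return -sum(v * math.log2(v) for v in q if v > 0)

    hxy = H(p.ravel())
    hx = H(px)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * px[j] > 0 and p[i, j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * px[j] > 0
    )
    f = {}
    f["joint_maximum"] = p.max()
    f["joint_average"] = mu
    f["joint_variance"] = var
    f["joint_entropy"] = hxy
    f["difference_average"] = da
    f["difference_variance"] = sum((k - da) ** 2 * pd[k] for k in range(ng))
    f["difference_entropy"] = H(pd)
    f["sum_average"] = sa
    f["sum_variance"] = sum((k + 2 - sa) ** 2 * ps[k] for k in range(len(ps)))
    f["sum_entropy"] = H(ps)
    f["angular_second_moment"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    f["dissimilarity"] = sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng))
    f["inverse_difference"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    f["inverse_difference_normalized"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    f["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    f["inverse_difference_moment_normalized"] = sum(
        p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    f["inverse_variance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    if var > 0:
        f["correlation"] = (
            sum((i + 1 - mu) * (j + 1 - mu) * p[i, j] for i in range(ng) for j in range(ng))
            / var
        )
    else:
        f["correlation"] = 1.0
    f["autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)
    )
    for name, power in (("cluster_tendency", 2), ("cluster_shade", 3), ("cluster_prominence", 4)):
        f[name] = sum(
            (i + 1 + j + 1 - 2 * mu) ** power * p[i, j] for i in range(ng) for j in range(ng)
        )
    f["information_correlation_1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    f["information_correlation_2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    return f


def length_matrix_feats(mat, nv):
    """The 16 functional forms shared by GLRLM/GLSZM/GLDZM/NGLDM, generic keys."""
    ng, w = mat.shape
    ns = mat.sum()
    ri = [sum(mat[i, j] for j in range(w)) for i in range(ng)]
    rj = [sum(mat[i, j] for i in range(ng)) for j in range(w)]
    mu_i = sum((i + 1) * mat[i, j] for i in range(ng) for j in range(w)) / ns
    mu_j = sum((j + 1) * mat[i, j] for i in range(ng) for j in range(w)) / ns
    f = {}
    f["sje"] = sum(mat[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(w)) / ns
    f["lje"] = sum(mat[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(w)) / ns
    f["lgle"] = sum(ri[i] / (i + 1) ** 2 for i in range(ng)) / ns
    f["hgle"] = sum(ri[i] * (i + 1) ** 2 for i in range(ng)) / ns
    f["sjlge"] = sum(
        mat[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(w)
    ) / ns
    f["sjhge"] = sum(
        mat[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(w)
    ) / ns
    f["ljlge"] = sum(
        mat[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(w)
    ) / ns
    f["ljhge"] = sum(
        mat[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(w)
    ) / ns
    f["gln"] = sum(r**2 for r in ri) / ns
    f["glnn"] = sum(r**2 for r in ri) / ns**2
    f["jn"] = sum(r**2 for r in rj) / ns
    f["jnn"] = sum(r**2 for r in rj) / ns**2
    f["pct"] = ns / nv
    f["glv"] = sum((i + 1 - mu_i) ** 2 * mat[i, j] for i in range(ng) for j in range(w)) / ns
    f["jv"] = sum((j + 1 - mu_j) ** 2 * mat[i, j] for i in range(ng) for j in range(w)) / ns
    f["ent"] = -sum(
        mat[i, j] / ns * math.log2(mat[i, j] / ns)
        for i in range(ng)
        for j in range(w)
        if mat[i, j] > 0
    )
    return f


_GENERIC = ["sje", "lje", "lgle", "hgle", "sjlge", "sjhge", "ljlge", "ljhge",
            "gln", "glnn", "jn", "jnn", "pct", "glv", "jv", "ent"]

GLRLM_NAMES = [
    "short_run_emphasis", "long_run_emphasis", "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis", "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis", "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage",
    "gray_level_variance", "run_length_variance", "run_entropy",
]
GLSZM_NAMES = [
    "small_zone_emphasis", "large_zone_emphasis", "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis", "small_zone_low_gray_level_emphasis",
    "small_zone_high_gray_level_emphasis", "large_zone_low_gray_level_emphasis",
    "large_zone_high_gray_level_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "zone_size_nonuniformity",
    "zone_size_nonuniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_size_variance", "zone_size_entropy",
]
GLDZM_NAMES = [
    "small_distance_emphasis", "large_distance_emphasis", "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis", "small_distance_low_gray_level_emphasis",
    "small_distance_high_gray_level_emphasis", "large_distance_low_gray_level_emphasis",
    "large_distance_high_gray_level_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "zone_distance_nonuniformity",
    "zone_distance_nonuniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_distance_variance", "zone_distance_entropy",
]
NGLDM_NAMES = [
    "low_dependence_emphasis", "high_dependence_emphasis", "low_gray_level_count_emphasis",
    "high_gray_level_count_emphasis", "low_dependence_low_gray_level_emphasis",
    "low_dependence_high_gray_level_emphasis", "high_dependence_low_gray_level_emphasis",
    "high_dependence_high_gray_level_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "dependence_count_nonuniformity",
    "dependence_count_nonuniformity_normalized", "dependence_count_percentage",
    "gray_level_variance", "dependence_count_variance", "dependence_count_entropy",
]


def _named(mat, nv, names):
    generic = length_matrix_feats(mat, nv)
    return {name: generic[g] for g, name in zip(_GENERIC, names)}


def _trim(mat):
    """Drop trailing all-zero columns (but keep at least one)."""
    w = mat.shape[1]
    while w > 1 and not mat[:, w - 1].any():
        w -= 1
    return mat[:, :w]


def ngtdm_feats(levels, ng):
    n, s, nv = ngtdm_components(levels, ng)
    p = n / nv
    idx = [i for i in range(ng) if p[i] > 0]
    ngp = len(idx)
    denom = sum(p[i] * s[i] for i in range(ng))
    coarseness = min(1.0 / denom if denom > 0 else 1e6, 1e6)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in idx for j in idx)
            / (ngp * (ngp - 1))
            * sum(s)
            / nv
        )
        busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in idx for j in idx)
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in idx
            for j in idx
        ) / nv
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in idx for j in idx) / sum(s)
            if sum(s) > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def intensity_feats(data, levels, ng):
    x = np.sort(data[~np.isnan(data)])
    n = x.size
    mean = x.sum() / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)

    def pctl(q):
        # linear interpolation between order statistics
        h = (n - 1) * q / 100.0
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    p10, p25, p50, p75, p90 = (pctl(q) for q in (10, 25, 50, 75, 90))
    core = x[(x >= p10) & (x <= p90)]
    f = {
        "stat_mean": mean,
        "stat_variance": var,
        "stat_skewness": (sum((v - mean) ** 3 for v in x) / n / sd**3) if sd > 0 else 0.0,
        "stat_kurtosis": (sum((v - mean) ** 4 for v in x) / n / sd**4 - 3) if sd > 0 else 0.0,
        "stat_median": p50,
        "stat_minimum": x[0],
        "stat_p10": p10,
        "stat_p90": p90,
        "stat_maximum": x[-1],
        "stat_iqr": p75 - p25,
        "stat_range": x[-1] - x[0],
        "stat_mad": sum(abs(v - mean) for v in x) / n,
        "stat_rmad": sum(abs(v - core.mean()) for v in core) / core.size,
        "stat_medad": sum(abs(v - p50) for v in x) / n,
        "stat_cov": sd / mean if mean != 0 else 0.0,
        "stat_qcod": (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else 0.0,
        "stat_energy": sum(v**2 for v in x),
        "stat_rms": math.sqrt(sum(v**2 for v in x) / n),
    }
    lv = np.sort(levels[levels > 0]).astype(float)
    counts = [int((lv == k).sum()) for k in range(1, ng + 1)]
    pr = [c / lv.size for c in counts]
    lmean = lv.sum() / lv.size
    m = lv.size
    lmed = (lv[m // 2] if m % 2 else (lv[m // 2 - 1] + lv[m // 2]) / 2)
    f.update({
        "hist_mean": lmean,
        "hist_variance": sum((v - lmean) ** 2 for v in lv) / m,
        "hist_median": lmed,
        "hist_range": lv[-1] - lv[0],
        "hist_entropy": -sum(q * math.log2(q) for q in pr if q > 0),
        "hist_uniformity": sum(q**2 for q in pr),
        "hist_mode": float(int(np.argmax(counts)) + 1),
    })
    return f


def feature_vector(data, window, bin_width):
    """All 161 features, brute force, same canonical naming as the package."""
    levels, ng = discretize(data, window[0], window[1], bin_width)
    nv = int((levels > 0).sum())
    out = intensity_feats(data, levels, ng)

    width = max(levels.shape) * 3
    glcm_mats = [glcm_counts(levels, ng, d) for d in DIRS]
    glcm_mats_nz = [m for m in glcm_mats if m.sum() > 0]
    per_dir = [glcm_feats(m) for m in glcm_mats_nz]
    for key in per_dir[0]:
        out[f"glcm_averaged_{key}"] = sum(f[key] for f in per_dir) / len(per_dir)
    merged = glcm_feats(sum(glcm_mats_nz))
    out.update({f"glcm_merged_{k}": v for k, v in merged.items()})

    rlms = [_trim(rlm_matrix(levels, ng, d, width)) for d in DIRS]
    per_dir = [_named(_trim(m), nv, GLRLM_NAMES) for m in rlms]
    for key in GLRLM_NAMES:
        out[f"glrlm_averaged_{key}"] = sum(f[key] for f in per_dir) / len(per_dir)
    w = max(m.shape[1] for m in rlms)
    summed = sum(np.pad(m, ((0, 0), (0, w - m.shape[1]))) for m in rlms)
    out.update({
        f"glrlm_merged_{k}": v
        for k, v in _named(summed, nv * len(DIRS), GLRLM_NAMES).items()
    })

    zlist = zones(levels)
    max_size = max(z[1] for z in zlist)
    max_dist = max(z[2] for z in zlist)
    szm = np.zeros((ng, max_size))
    dzm = np.zeros((ng, max_dist))
    for lv, size, dist in zlist:
        szm[lv - 1, size - 1] += 1
        dzm[lv - 1, dist - 1] += 1
    out.update({f"glszm_{k}": v for k, v in _named(szm, nv, GLSZM_NAMES).items()})
    out.update({f"gldzm_{k}": v for k, v in _named(dzm, nv, GLDZM_NAMES).items()})

    out.update({f"ngtdm_{k}": v for k, v in ngtdm_feats(levels, ng).items()})
    nmat = _trim(ngldm_matrix(levels, ng))
    ngl = _named(nmat, nv, NGLDM_NAMES)
    ns = nmat.sum()
    ngl["dependence_count_energy"] = sum(
        (nmat[i, j] / ns) ** 2 for i in range(nmat.shape[0]) for j in range(nmat.shape[1])
    )
    out.update({f"ngldm_{k}": v for k, v in ngl.items()})
    return out
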