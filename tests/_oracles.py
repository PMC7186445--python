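"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit loops over voxel pairs,
runs, and polygon tests, kept free of any code path shared with the
package.
"""

from __future__ import annotations

import numpy as np

DIRECTIONS = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


def glcm_brute(levels: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Enumerate every in-mask voxel pair per direction; symmetric merged."""
    nz, ny, nx = levels.shape
    counts = np.zeros((n_bins, n_bins), dtype=float)
    for dz, dy, dx in DIRECTIONS:
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    if not mask[z, y, x]:
                        continue
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and mask[z2, y2, x2]:
                        i, j = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                        counts[i, j] += 1
                        counts[j, i] += 1
    return counts / counts.sum()


def glcm_features_brute(levels, mask, n_bins) -> dict:
    """Direct evaluation of every co-occurrence statistic from the matrix."""
    p = glcm_brute(levels, mask, n_bins)
    n = n_bins
    feats = {}
    i_idx = np.arange(1, n + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_i = sum(i * px[i - 1] for i in i_idx)
    mu_j = sum(j * py[j - 1] for j in i_idx)
    var_i = sum((i - mu_i) ** 2 * px[i - 1] for i in i_idx)
    var_j = sum((j - mu_j) ** 2 * py[j - 1] for j in i_idx)

    js = {}
    for name in ("joint_maximum", "joint_average", "joint_variance", "joint_entropy",
                 "angular_second_moment", "contrast", "dissimilarity",
                 "inverse_difference", "inverse_difference_normalized",
                 "inverse_difference_moment", "inverse_difference_moment_normalized",
                 "inverse_variance", "correlation", "autocorrelation",
                 "cluster_tendency", "cluster_shade", "cluster_prominence"):
        js[name] = 0.0
    for i in i_idx:
        for j in i_idx:
            pij = p[i - 1, j - 1]
            if pij == 0:
                continue
            d = abs(i - j)
            js["joint_maximum"] = max(js["joint_maximum"], pij)
            js["joint_average"] += i * pij
            js["joint_variance"] += (i - mu_i) ** 2 * pij
            js["joint_entropy"] -= pij * np.log2(pij)
            js["angular_second_moment"] += pij**2
            js["contrast"] += d**2 * pij
            js["dissimilarity"] += d * pij
            js["inverse_difference"] += pij / (1 + d)
            js["inverse_difference_normalized"] += pij / (1 + d / n)
            js["inverse_difference_moment"] += pij / (1 + d**2)
            js["inverse_difference_moment_normalized"] += pij / (1 + (d / n) ** 2)
            if d > 0:
                js["inverse_variance"] += pij / d**2
            js["autocorrelation"] += i * j * pij
            c = i + j - mu_i - mu_j
            js["cluster_tendency"] += c**2 * pij
            js["cluster_shade"] += c**3 * pij
            js["cluster_prominence"] += c**4 * pij
    if var_i > 0 and var_j > 0:
        js["correlation"] = (js["autocorrelation"] - mu_i * mu_j) / np.sqrt(var_i * var_j)
    feats.update(js)

    psum = np.zeros(2 * n + 1)
    pdiff = np.zeros(n)
    for i in i_idx:
        for j in i_idx:
            psum[i + j] += p[i - 1, j - 1]
            pdiff[abs(i - j)] += p[i - 1, j - 1]
    sa = sum(k * psum[k] for k in range(2 * n + 1))
    feats["sum_average"] = sa
    feats["sum_variance"] = sum((k - sa) ** 2 * psum[k] for k in range(2 * n + 1))
    feats["sum_entropy"] = -sum(v * np.log2(v) for v in psum if v > 0)
    da = sum(k * pdiff[k] for k in range(n))
    feats["difference_average"] = da
    feats["difference_variance"] = sum((k - da) ** 2 * pdiff[k] for k in range(n))
    feats["difference_entropy"] = -sum(v * np.log2(v) for v in pdiff if v > 0)

    hxy = feats["joint_entropy"]
    hxy1 = hxy2 = 0.0
    for i in i_idx:
        for j in i_idx:
            q = px[i - 1] * py[j - 1]
            if q > 0:
                if p[i - 1, j - 1] > 0:
                    hxy1 -= p[i - 1, j - 1] * np.log2(q)
                hxy2 -= q * np.log2(q)
    hx = -sum(v * np.log2(v) for v in px if v > 0)
    feats["information_correlation_1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    feats["information_correlation_2"] = float(np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy)))))
    return feats


def glrlm_brute(levels, mask, n_bins, directions=None) -> np.ndarray:
    """Explicit run scan per direction: walk each line voxel by voxel."""
    directions = directions or DIRECTIONS
    nz, ny, nx = levels.shape
    max_len = max(levels.shape)
    R = np.zeros((n_bins, max_len), dtype=float)
    for d in directions:
        dz, dy, dx = d
        visited = np.zeros(levels.shape, dtype=bool)
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    if not mask[z, y, x] or visited[z, y, x]:
                        continue
                    pz, py_, px_ = z - dz, y - dy, x - dx
                    starts_run = not (
                        0 <= pz < nz and 0 <= py_ < ny and 0 <= px_ < nx
                        and mask[pz, py_, px_]
                        and levels[pz, py_, px_] == levels[z, y, x]
                    )
                    if not starts_run:
                        continue
                    length = 0
                    cz, cy, cx = z, y, x
                    lv = levels[z, y, x]
                    while (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx
                           and mask[cz, cy, cx] and levels[cz, cy, cx] == lv):
                        visited[cz, cy, cx] = True
                        length += 1
                        cz, cy, cx = cz + dz, cy + dy, cx + dx
                    R[lv - 1, length - 1] += 1
        visited[:] = False
    return R


def glrlm_features_brute(levels, mask, n_bins, n_directions=13) -> dict:
    R = glrlm_brute(levels, mask, n_bins)
    nr = R.sum()
    nv = mask.sum()
    feats = {k: 0.0 for k in (
        "short_run_emphasis", "long_run_emphasis", "low_gray_level_run_emphasis",
        "high_gray_level_run_emphasis", "short_run_low_gray_level_emphasis",
        "short_run_high_gray_level_emphasis", "long_run_low_gray_level_emphasis",
        "long_run_high_gray_level_emphasis", "gray_level_variance")}
    mu_g = 0.0
    for i in range(1, n_bins + 1):
        for j in range(1, R.shape[1] + 1):
            mu_g += i * R[i - 1, j - 1] / nr
    for i in range(1, n_bins + 1):
        for j in range(1, R.shape[1] + 1):
            r = R[i - 1, j - 1]
            if r == 0:
                continue
            feats["short_run_emphasis"] += r / j**2 / nr
            feats["long_run_emphasis"] += r * j**2 / nr
            feats["low_gray_level_run_emphasis"] += r / i**2 / nr
            feats["high_gray_level_run_emphasis"] += r * i**2 / nr
            feats["short_run_low_gray_level_emphasis"] += r / (i**2 * j**2) / nr
            feats["short_run_high_gray_level_emphasis"] += r * i**2 / j**2 / nr
            feats["long_run_low_gray_level_emphasis"] += r * j**2 / i**2 / nr
            feats["long_run_high_gray_level_emphasis"] += r * i**2 * j**2 / nr
            feats["gray_level_variance"] += (i - mu_g) ** 2 * r / nr
    r_g = R.sum(axis=1)
    r_l = R.sum(axis=0)
    feats["gray_level_non_uniformity"] = float((r_g**2).sum() / nr)
    feats["gray_level_non_uniformity_normalized"] = float((r_g**2).sum() / nr**2)
    feats["run_length_non_uniformity"] = float((r_l**2).sum() / nr)
    feats["run_length_non_uniformity_normalized"] = float((r_l**2).sum() / nr**2)
    feats["run_percentage"] = float(nr / (n_directions * nv))
    return feats


def point_in_polygon(x: float, y: float, poly) -> bool:
    """Even-odd ray casting, independent of matplotlib."""
    inside = False
    n = len(poly)
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def pairwise_auc(scores, labels) -> float:
    """Enumerate all positive-negative pairs; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
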