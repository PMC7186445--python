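"""IBSI-style radiomic features: shape, first-order, GLCM and GLRLM.

The default catalog yields, per patient, 21 shape features for each of the
two ROIs (breast, PTV) plus 57 intensity/texture features (18 first-order +
25 co-occurrence + 14 run-length) for every combination of image (RED,
BED), ROI, and filter (none, Gaussian, LoG, median):

    21·2 + 57·2·2·4 = 954 columns.

Texture matrices follow the merged 3D convention: distance-1 voxel pairs
over the 13 unique directions, symmetrized and summed into a single matrix
before normalization (GLCM), and runs per direction summed into a single
run-length matrix (GLRLM).  Both the run-length non-uniformity (RLN) and
its normalized variant (RLNN) are emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from .grids import ROIMask, VolumeGrid
from .preprocess import DEFAULT_FILTERS, DiscretizedVolume, FilterSpec, apply_filter, discretize

__all__ = [
    "DIRECTIONS_3D",
    "FIRSTORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "SHAPE_NAMES",
    "FeatureCatalog",
    "default_catalog",
    "shape_features",
    "firstorder_features",
    "cooccurrence_matrix",
    "glcm_features",
    "runlength_matrix",
    "glrlm_features",
    "extract_all",
]

# 13 unique distance-1 3D directions (z, y, x), first nonzero component +1
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
)

SHAPE_NAMES = (
    "volume_voxel",
    "volume_mesh",
    "surface_area",
    "surface_to_volume_ratio",
    "sphericity",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "asphericity",
    "max_3d_diameter",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
    "volume_density_aabb",
    "area_density_aabb",
    "volume_density_ellipsoid",
    "area_density_ellipsoid",
    "centre_of_mass_shift",
    "max_2d_diameter_axial",
)

FIRSTORDER_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "p10",
    "p90",
    "maximum",
    "range",
    "interquartile_range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "energy",
    "root_mean_square",
    "entropy",
    "uniformity",
    "coefficient_of_variation",
)

GLCM_NAMES = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "information_correlation_1",
    "information_correlation_2",
)

GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "run_percentage",
    "gray_level_variance",
)


# ---------------------------------------------------------------------------
# shape


def _mesh(mask: np.ndarray, spacing_xyz) -> tuple[np.ndarray, np.ndarray]:
    # the indicator is slightly smoothed (0.8 voxel) before meshing so the
    # 0.5-isosurface does not carry the staircase area of the raw voxel mask
    from scipy import ndimage

    sz, sy, sx = spacing_xyz[2], spacing_xyz[1], spacing_xyz[0]
    padded = np.pad(mask.astype(float), 2)
    smooth = ndimage.gaussian_filter(padded, 0.8)
    if smooth.max() <= 0.5:  # tiny masks: fall back to the raw voxel surface
        smooth = padded
    verts, faces, _, _ = measure.marching_cubes(smooth, level=0.5, spacing=(sz, sy, sx))
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 4 and points.shape[1] <= 3:
        try:
            hull = ConvexHull(points, qhull_options="QJ")
            points = points[hull.vertices]
        except Exception:
            pass
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    # Thomsen's approximation, exact for spheres
    p = 1.6075
    if min(a, b, c) <= 0:
        return 0.0
    s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * np.pi * s ** (1.0 / p)


def shape_features(
    mask: ROIMask,
    spacing: tuple[float, float, float] | None = None,
    intensity: VolumeGrid | None = None,
) -> dict[str, float]:
    """The 21 morphological features of a binary ROI.

    ``centre_of_mass_shift`` is the distance (mm) between the geometric
    centroid and the intensity-weighted centroid; it is 0 when no intensity
    volume is supplied.
    """
    spacing = spacing or mask.spacing
    m = mask.values
    n = int(m.sum())
    if n == 0:
        raise ValueError(f"mask {mask.roi_name!r} is empty")
    if n == 1:
        warnings.warn("single-voxel mask: surface features use the voxel cube", stacklevel=2)
    voxvol = float(np.prod(spacing))
    v_vox = n * voxvol

    verts, faces = _mesh(m, spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    v_mesh = _mesh_volume(verts, faces)
    v = v_mesh if v_mesh > 0 else v_vox

    sphericity = (36.0 * np.pi * v**2) ** (1.0 / 3.0) / area
    compactness1 = v / (np.sqrt(np.pi) * area**1.5)
    compactness2 = 36.0 * np.pi * v**2 / area**3
    sph_dis = 1.0 / sphericity
    asphericity = (area**3 / (36.0 * np.pi * v**2)) ** (1.0 / 3.0) - 1.0

    zz, yy, xx = np.nonzero(m)
    coords = np.column_stack(
        [xx * spacing[0], yy * spacing[1], zz * spacing[2]]
    ).astype(float)
    centroid = coords.mean(axis=0)
    if n > 1:
        cov = np.cov(coords.T)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    lo = coords.min(axis=0) - np.asarray(spacing) / 2.0
    hi = coords.max(axis=0) + np.asarray(spacing) / 2.0
    ext = hi - lo
    v_aabb = float(np.prod(ext))
    a_aabb = float(2.0 * (ext[0] * ext[1] + ext[0] * ext[2] + ext[1] * ext[2]))

    a_s, b_s, c_s = 2.0 * np.sqrt(eig)  # ellipsoid semi-axes
    v_ell = 4.0 / 3.0 * np.pi * a_s * b_s * c_s
    a_ell = _ellipsoid_area(a_s, b_s, c_s)

    com_shift = 0.0
    if intensity is not None:
        w = intensity.values[m].astype(float)
        if np.abs(w).sum() > 0:
            wc = (coords * w[:, None]).sum(axis=0) / w.sum()
            com_shift = float(np.linalg.norm(wc - centroid))

    max3d = _max_pairwise(coords)
    max2d = _max_pairwise(np.unique(coords[:, :2], axis=0))

    return {
        "volume_voxel": v_vox,
        "volume_mesh": v_mesh,
        "surface_area": area,
        "surface_to_volume_ratio": area / v,
        "sphericity": float(sphericity),
        "compactness1": float(compactness1),
        "compactness2": float(compactness2),
        "spherical_disproportion": float(sph_dis),
        "asphericity": float(asphericity),
        "max_3d_diameter": max3d,
        "major_axis_length": float(major),
        "minor_axis_length": float(minor),
        "least_axis_length": float(least),
        "elongation": elongation,
        "flatness": flatness,
        "volume_density_aabb": v_vox / v_aabb,
        "area_density_aabb": area / a_aabb if a_aabb > 0 else 0.0,
        "volume_density_ellipsoid": v_vox / v_ell if v_ell > 0 else 0.0,
        "area_density_ellipsoid": area / a_ell if a_ell > 0 else 0.0,
        "centre_of_mass_shift": com_shift,
        "max_2d_diameter_axial": max2d,
    }


# ---------------------------------------------------------------------------
# first order


def firstorder_features(
    volume: VolumeGrid, mask: ROIMask, n_bins: int = 64
) -> dict[str, float]:
    """First-order statistics of in-mask intensities.

    Percentiles use linear interpolation; kurtosis is the excess (−3)
    convention; entropy and uniformity are computed on the ``n_bins``
    equal-width histogram of in-mask values.  A zero-variance ROI yields
    skewness and kurtosis of 0 (degenerate, flagged via warning).
    """
    mask.check_aligned(volume)
    x = volume.values[mask.values].astype(float)
    if x.size < 2:
        raise ValueError("first-order features need at least 2 in-mask voxels")
    mean = float(x.mean())
    var = float(x.var())
    if var == 0:
        warnings.warn("zero-variance ROI: skewness/kurtosis set to 0", stacklevel=2)
        skew = kurt = 0.0
    else:
        sd = np.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2 - 3.0)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    sel = (x >= p10) & (x <= p90)
    robust = x[sel]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        hist, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
        p = hist / hist.sum()
        nz = p[p > 0]
        entropy = float(-np.sum(nz * np.log2(nz)))
        uniformity = float(np.sum(p**2))
    else:
        entropy, uniformity = 0.0, 1.0

    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": float(p50),
        "minimum": lo,
        "p10": float(p10),
        "p90": float(p90),
        "maximum": hi,
        "range": hi - lo,
        "interquartile_range": float(p75 - p25),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mean))),
        "robust_mean_absolute_deviation": rmad,
        "energy": float(np.sum(x**2)),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "entropy": entropy,
        "uniformity": uniformity,
        "coefficient_of_variation": float(np.sqrt(var) / mean) if mean != 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# GLCM


def cooccurrence_matrix(
    disc: DiscretizedVolume,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Symmetric merged distance-1 co-occurrence probability matrix.

    Pairs from all directions are symmetrized and summed into a single
    ``n_bins × n_bins`` matrix, then normalized to sum to 1.
    """
    n = disc.n_bins
    lv = disc.levels
    m = disc.mask
    counts = np.zeros((n, n), dtype=np.int64)
    for dz, dy, dx in directions:
        nz, ny, nx = lv.shape

        def sl(d, size):
            if d == 0:
                return slice(0, size), slice(0, size)
            if d > 0:
                return slice(0, size - d), slice(d, size)
            return slice(-d, size), slice(0, size + d)

        (az, bz), (ay, by), (ax, bx) = sl(dz, nz), sl(dy, ny), sl(dx, nx)
        la = lv[az, ay, ax]
        lb = lv[bz, by, bx]
        valid = m[az, ay, ax] & m[bz, by, bx]
        i = la[valid] - 1
        j = lb[valid] - 1
        flat = np.bincount(i * n + j, minlength=n * n).reshape(n, n)
        counts += flat + flat.T
    total = counts.sum()
    if total == 0:
        raise ValueError("co-occurrence matrix is empty (ROI has < 2 connected voxels)")
    return counts.astype(float) / total


def glcm_features(
    disc: DiscretizedVolume,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> dict[str, float]:
    """The 25 co-occurrence features of the merged symmetric GLCM."""
    if int(disc.mask.sum()) < 2:
        raise ValueError("GLCM needs at least 2 in-ROI voxels")
    p = cooccurrence_matrix(disc, directions)
    n = disc.n_bins
    idx = np.arange(1, n + 1, dtype=float)
    ii = idx[:, None] * np.ones((1, n))
    jj = ii.T

    px = p.sum(axis=1)
    mu_i = float(np.sum(idx * px))
    mu_j = mu_i  # symmetric
    var_i = float(np.sum((idx - mu_i) ** 2 * px))
    sd_i = np.sqrt(var_i)

    diff = np.abs(ii - jj)
    joint_entropy = float(-np.sum(p[p > 0] * np.log2(p[p > 0])))

    # sum / difference marginals
    psum = np.zeros(2 * n + 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), p.ravel())
    pdiff = np.zeros(n)
    np.add.at(pdiff, diff.astype(int).ravel(), p.ravel())
    ks = np.arange(2 * n + 1, dtype=float)
    kd = np.arange(n, dtype=float)
    sum_avg = float(np.sum(ks * psum))
    sum_var = float(np.sum((ks - sum_avg) ** 2 * psum))
    sum_ent = float(-np.sum(psum[psum > 0] * np.log2(psum[psum > 0])))
    diff_avg = float(np.sum(kd * pdiff))
    diff_var = float(np.sum((kd - diff_avg) ** 2 * pdiff))
    diff_ent = float(-np.sum(pdiff[pdiff > 0] * np.log2(pdiff[pdiff > 0])))

    if var_i > 0:
        correlation = float((np.sum(ii * jj * p) - mu_i * mu_j) / (sd_i * sd_i))
    else:
        warnings.warn("degenerate GLCM (single gray level): correlation set to 0", stacklevel=2)
        correlation = 0.0

    off = diff > 0
    inverse_variance = float(np.sum(p[off] / diff[off] ** 2))

    # information measures of correlation
    outer = px[:, None] * px[None, :]
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[pos] * np.log2(outer[pos])))
    pos2 = outer > 0
    hxy2 = float(-np.sum(outer[pos2] * np.log2(outer[pos2])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    imc1 = (joint_entropy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    cdev = ii + jj - mu_i - mu_j
    return {
        "joint_maximum": float(p.max()),
        "joint_average": mu_i,
        "joint_variance": float(np.sum((ii - mu_i) ** 2 * p)),
        "joint_entropy": joint_entropy,
        "angular_second_moment": float(np.sum(p**2)),
        "contrast": float(np.sum(diff**2 * p)),
        "dissimilarity": float(np.sum(diff * p)),
        "inverse_difference": float(np.sum(p / (1.0 + diff))),
        "inverse_difference_normalized": float(np.sum(p / (1.0 + diff / n))),
        "inverse_difference_moment": float(np.sum(p / (1.0 + diff**2))),
        "inverse_difference_moment_normalized": float(np.sum(p / (1.0 + (diff / n) ** 2))),
        "inverse_variance": inverse_variance,
        "correlation": correlation,
        "autocorrelation": float(np.sum(ii * jj * p)),
        "cluster_tendency": float(np.sum(cdev**2 * p)),
        "cluster_shade": float(np.sum(cdev**3 * p)),
        "cluster_prominence": float(np.sum(cdev**4 * p)),
        "sum_average": sum_avg,
        "sum_variance": sum_var,
        "sum_entropy": sum_ent,
        "difference_average": diff_avg,
        "difference_variance": diff_var,
        "difference_entropy": diff_ent,
        "information_correlation_1": float(imc1),
        "information_correlation_2": imc2,
    }


# ---------------------------------------------------------------------------
# GLRLM


def runlength_matrix(
    disc: DiscretizedVolume,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Run-length counts ``r(i, j)`` summed over directions.

    A run is a maximal sequence of in-ROI voxels of equal level along a
    direction; leaving the ROI breaks a run.  Rows are gray levels
    1..n_bins, columns run lengths 1..max.
    """
    lv = disc.levels
    m = disc.mask
    zz, yy, xx = np.nonzero(m)
    if zz.size == 0:
        raise ValueError("run-length matrix needs at least 1 in-ROI voxel")
    levels = lv[zz, yy, xx]
    max_len = max(lv.shape)
    R = np.zeros((disc.n_bins, max_len), dtype=np.int64)
    for dz, dy, dx in directions:
        t = zz if dz else (yy if dy else xx)
        k1 = zz - t * dz
        k2 = yy - t * dy
        k3 = xx - t * dx
        order = np.lexsort((t, k3, k2, k1))
        ts, ls = t[order], levels[order]
        key = np.column_stack([k1, k2, k3])[order]
        if ts.size == 1:
            R[ls[0] - 1, 0] += 1
            continue
        same_line = np.all(key[1:] == key[:-1], axis=1) & (ts[1:] == ts[:-1] + 1)
        same_run = same_line & (ls[1:] == ls[:-1])
        breaks = np.nonzero(~same_run)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [ts.size - 1]])
        lengths = ends - starts + 1
        np.add.at(R, (ls[starts] - 1, lengths - 1), 1)
    return R


def glrlm_features(
    disc: DiscretizedVolume,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> dict[str, float]:
    """The 14 run-length features of the direction-merged GLRLM."""
    R = runlength_matrix(disc, directions).astype(float)
    nr = R.sum()
    nv = int(disc.mask.sum())
    gi = np.arange(1, R.shape[0] + 1, dtype=float)  # gray levels
    rj = np.arange(1, R.shape[1] + 1, dtype=float)  # run lengths
    r_g = R.sum(axis=1)
    r_l = R.sum(axis=0)
    p = R / nr
    mu_g = float(np.sum(gi * r_g) / nr)

    def emph(wg, wl):
        return float(np.sum(R * np.outer(wg, wl)) / nr)

    return {
        "short_run_emphasis": float(np.sum(r_l / rj**2) / nr),
        "long_run_emphasis": float(np.sum(r_l * rj**2) / nr),
        "low_gray_level_run_emphasis": float(np.sum(r_g / gi**2) / nr),
        "high_gray_level_run_emphasis": float(np.sum(r_g * gi**2) / nr),
        "short_run_low_gray_level_emphasis": emph(1.0 / gi**2, 1.0 / rj**2),
        "short_run_high_gray_level_emphasis": emph(gi**2, 1.0 / rj**2),
        "long_run_low_gray_level_emphasis": emph(1.0 / gi**2, rj**2),
        "long_run_high_gray_level_emphasis": emph(gi**2, rj**2),
        "gray_level_non_uniformity": float(np.sum(r_g**2) / nr),
        "gray_level_non_uniformity_normalized": float(np.sum(r_g**2) / nr**2),
        "run_length_non_uniformity": float(np.sum(r_l**2) / nr),
        "run_length_non_uniformity_normalized": float(np.sum(r_l**2) / nr**2),
        "run_percentage": float(nr / (len(directions) * nv)),
        "gray_level_variance": float(np.sum(p * ((gi - mu_g) ** 2)[:, None])),
    }


# ---------------------------------------------------------------------------
# catalog / extraction


@dataclass(frozen=True)
class FeatureDescriptor:
    family: str  # shape | firstorder | glcm | glrlm
    feature_name: str
    image: str | None  # red | bed | None for shape
    roi: str  # breast | ptv
    filter: FilterSpec | None

    @property
    def column(self) -> str:
        if self.family == "shape":
            return f"shape_{self.roi}_{self.feature_name}"
        assert self.image is not None and self.filter is not None
        return f"{self.image}_{self.filter.kind}_{self.roi}_{self.family}_{self.feature_name}"


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered list of feature descriptors defining the output columns."""

    descriptors: tuple[FeatureDescriptor, ...]
    n_bins: int = 64

    @property
    def columns(self) -> list[str]:
        return [d.column for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)


def default_catalog(
    images: tuple[str, ...] = ("red", "bed"),
    rois: tuple[str, ...] = ("breast", "ptv"),
    filters: tuple[FilterSpec, ...] = DEFAULT_FILTERS,
    n_bins: int = 64,
) -> FeatureCatalog:
    """The full catalog: 21·|rois| shape + 57·|images|·|rois|·|filters| texture."""
    desc: list[FeatureDescriptor] = []
    for roi in rois:
        for name in SHAPE_NAMES:
            desc.append(FeatureDescriptor("shape", name, None, roi, None))
    for image in images:
        for roi in rois:
            for filt in filters:
                for name in FIRSTORDER_NAMES:
                    desc.append(FeatureDescriptor("firstorder", name, image, roi, filt))
                for name in GLCM_NAMES:
                    desc.append(FeatureDescriptor("glcm", name, image, roi, filt))
                for name in GLRLM_NAMES:
                    desc.append(FeatureDescriptor("glrlm", name, image, roi, filt))
    cols = [d.column for d in desc]
    assert len(set(cols)) == len(cols), "catalog columns must be unique"
    return FeatureCatalog(tuple(desc), n_bins=n_bins)


def extract_all(
    red: VolumeGrid,
    bed: VolumeGrid,
    breast: ROIMask,
    ptv: ROIMask,
    catalog: FeatureCatalog | None = None,
) -> dict[str, float]:
    """Compute every catalog feature for one patient.

    Shape features are computed once per ROI (on the unfiltered RED for the
    centre-of-mass shift); each (image, ROI, filter) combination is
    filtered, discretized over its own in-ROI range, and fed to the three
    intensity families.
    """
    catalog = catalog or default_catalog()
    images = {"red": red, "bed": bed}
    rois = {"breast": breast, "ptv": ptv}
    for name, roi in rois.items():
        if roi is None or roi.voxel_count == 0:
            raise ValueError(f"missing or empty ROI {name!r}")
        for img in images.values():
            roi.check_aligned(img)

    # group texture work by (image, filter, roi) so each volume is filtered
    # and discretized once
    needed: dict[tuple[str, str, float, str], set[str]] = {}
    for d in catalog.descriptors:
        if d.family == "shape":
            continue
        assert d.filter is not None and d.image is not None
        key = (d.image, d.filter.kind, d.filter.scale, d.roi)
        needed.setdefault(key, set()).add(d.family)

    values: dict[str, float] = {}
    for roi_name, roi in rois.items():
        feats = shape_features(roi, intensity=images["red"])
        for fname, v in feats.items():
            values[f"shape_{roi_name}_{fname}"] = v

    filtered_cache: dict[tuple[str, str, float], VolumeGrid] = {}
    for (image, fkind, fscale, roi_name), families in sorted(needed.items()):
        fkey = (image, fkind, fscale)
        if fkey not in filtered_cache:
            filtered_cache[fkey] = apply_filter(images[image], FilterSpec(fkind, fscale))
        vol = filtered_cache[fkey]
        roi = rois[roi_name]
        prefix = f"{image}_{fkind}_{roi_name}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if "firstorder" in families:
                for fname, v in firstorder_features(vol, roi, catalog.n_bins).items():
                    values[f"{prefix}_firstorder_{fname}"] = v
            if "glcm" in families or "glrlm" in families:
                disc = discretize(vol, roi, catalog.n_bins)
                if "glcm" in families:
                    for fname, v in glcm_features(disc).items():
                        values[f"{prefix}_glcm_{fname}"] = v
                if "glrlm" in families:
                    for fname, v in glrlm_features(disc).items():
                        values[f"{prefix}_glrlm_{fname}"] = v

    return {col: values[col] for col in catalog.columns}
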