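"""Readers and writers for the supported volume formats.

DICOM CT series and RTDOSE grids are read with :mod:`pydicom`; masks are
rasterized from per-slice contour polygons (the geometry RTSTRUCT files
carry); NIfTI / NRRD research volumes are round-tripped through SimpleITK.
Only axial, axis-aligned geometries are supported — anything inconsistent
raises rather than being silently truncated.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
import SimpleITK as sitk
from matplotlib.path import Path as MplPath

from .grids import ROIMask, VolumeGrid

__all__ = [
    "read_ct_series",
    "read_dose",
    "rasterize_contours",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

_RESEARCH_EXTS = (".nii", ".nii.gz", ".nrrd", ".nhdr", ".mha")


def read_ct_series(directory: str | os.PathLike) -> VolumeGrid:
    """Read one axial CT series from a directory of DICOM slices.

    Slices are sorted by their along-axis (z) position regardless of file
    order, stored values are mapped to Hounsfield units via the rescale
    transform, and spacing is taken from the headers.
    """
    directory = Path(directory)
    slices = []
    for p in sorted(directory.iterdir()):
        if p.is_dir():
            continue
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if getattr(ds, "Modality", "CT") not in ("CT", ""):
            continue
        slices.append((p, ds))
    if not slices:
        raise ValueError(f"no readable CT slices in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for _, ds in slices}
    if len(uids) > 1:
        raise ValueError(f"directory {directory} mixes multiple series: {sorted(map(str, uids))}")
    for p, ds in slices:
        if "ImagePositionPatient" not in ds or "PixelSpacing" not in ds:
            raise ValueError(f"slice {p.name} is missing geometry tags")

    slices.sort(key=lambda item: float(item[1].ImagePositionPatient[2]))
    ref = slices[0][1]
    row_sp, col_sp = (float(v) for v in ref.PixelSpacing)
    zs = np.array([float(ds.ImagePositionPatient[2]) for _, ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0:
            raise ValueError("duplicate or non-increasing slice positions")
        if not np.allclose(dz, dz[0], atol=1e-3):
            raise ValueError("non-uniform slice spacing")
        slice_sp = float(dz[0])
    else:
        slice_sp = float(getattr(ref, "SliceThickness", 1.0))

    vol = np.empty((len(slices), ref.Rows, ref.Columns), dtype=float)
    for k, (p, ds) in enumerate(slices):
        if (ds.Rows, ds.Columns) != (ref.Rows, ref.Columns):
            raise ValueError(f"slice {p.name} has inconsistent in-plane shape")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        vol[k] = ds.pixel_array.astype(float) * slope + intercept

    origin = (
        float(ref.ImagePositionPatient[0]),
        float(ref.ImagePositionPatient[1]),
        float(zs[0]),
    )
    return VolumeGrid(vol, spacing=(col_sp, row_sp, slice_sp), origin=origin)


def read_dose(path: str | os.PathLike) -> VolumeGrid:
    """Read an RTDOSE grid; stored integers × DoseGridScaling give Gy."""
    ds = pydicom.dcmread(path)
    if "DoseGridScaling" not in ds:
        raise ValueError(f"{path}: missing DoseGridScaling tag")
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(float) * scaling
    if arr.ndim == 2:
        arr = arr[None]
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.array([float(v) for v in getattr(ds, "GridFrameOffsetVector", [0.0])])
    if len(offsets) > 1:
        dz = np.diff(offsets)
        if not np.allclose(dz, dz[0], atol=1e-3):
            raise ValueError("non-uniform dose grid frame offsets")
        slice_sp = float(abs(dz[0]))
    else:
        slice_sp = float(getattr(ds, "SliceThickness", row_sp) or row_sp)
    ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]) + float(offsets[0]))
    return VolumeGrid(arr, spacing=(col_sp, row_sp, slice_sp), origin=origin)


def rasterize_contours(
    contours: Iterable[tuple[float, Sequence[Sequence[float]]]],
    reference: VolumeGrid,
    roi_name: str = "roi",
) -> ROIMask:
    """Rasterize per-slice closed polygons (mm coordinates) onto a grid.

    ``contours`` yields ``(z_mm, [(x_mm, y_mm), ...])`` items.  A voxel is
    inside iff its center falls inside the polygon of its slice (even-odd
    rule); multiple polygons on a slice are unioned.  Polygons on slices
    outside the grid are skipped with a warning.
    """
    import warnings

    nz, ny, nx = reference.shape
    sx, sy, sz = reference.spacing
    ox, oy, oz = reference.origin
    mask = np.zeros(reference.shape, dtype=bool)

    xs = ox + np.arange(nx) * sx
    ys = oy + np.arange(ny) * sy
    xx, yy = np.meshgrid(xs, ys)  # (ny, nx)
    centers = np.column_stack([xx.ravel(), yy.ravel()])

    for z_mm, poly in contours:
        pts = np.asarray(poly, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3:
            raise ValueError("each contour needs at least 3 (x, y) vertices")
        k = (float(z_mm) - oz) / sz
        ki = int(round(k))
        if abs(k - ki) > 0.5 or not (0 <= ki < nz):
            warnings.warn(
                f"contour at z={z_mm} mm lies outside the grid; skipped", stacklevel=2
            )
            continue
        path = MplPath(np.vstack([pts, pts[:1]]), closed=True)
        inside = path.contains_points(centers).reshape(ny, nx)
        mask[ki] |= inside
    return ROIMask(mask, reference.spacing, reference.origin, roi_name=roi_name)


def _sitk_from_grid(grid: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values))
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    return img


def write_volume(grid: VolumeGrid, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI or NRRD, preserving spacing and origin."""
    path = str(path)
    if not path.endswith(_RESEARCH_EXTS):
        raise ValueError(
            f"unsupported volume extension for {path!r}; supported: {_RESEARCH_EXTS}"
        )
    sitk.WriteImage(_sitk_from_grid(grid), path)


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Read a NIfTI or NRRD volume written by :func:`write_volume`."""
    path = str(path)
    if not path.endswith(_RESEARCH_EXTS):
        raise ValueError(
            f"unsupported volume extension for {path!r}; supported: {_RESEARCH_EXTS}"
        )
    img = sitk.ReadImage(path)
    values = sitk.GetArrayFromImage(img)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={values.ndim}")
    return VolumeGrid(values, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def write_mask(mask: ROIMask, path: str | os.PathLike) -> None:
    write_volume(VolumeGrid(mask.values.astype(np.uint8), mask.spacing, mask.origin), path)


def read_mask(path: str | os.PathLike, roi_name: str = "roi") -> ROIMask:
    grid = read_volume(path)
    return ROIMask(grid.values > 0.5, grid.spacing, grid.origin, roi_name=roi_name)
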