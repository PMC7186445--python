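"""Volume containers and isotropic resampling.

The whole pipeline works on :class:`VolumeGrid` — a 3D scalar field with
voxel spacing and physical origin — holding, at different stages, the CT in
Hounsfield units, the relative electron density (RED), the physical dose in
Gy, or the biologically effective dose (BED).  :class:`ROIMask` is a binary
volume aligned to a reference grid (breast or PTV contour).

Conventions (fixed for the package): arrays are indexed ``[z, y, x]``;
``spacing`` and ``origin`` are ``(x, y, z)`` in mm; voxel ``(i, j, k)``
(z, y, x order) has its *center* at ``origin + index * spacing``; masks are
defined by center inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = ["VolumeGrid", "ROIMask", "resample", "resample_mask"]

AXIS_ORDER = "zyx"


@dataclass
class VolumeGrid:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Voxel values; must be finite.
    spacing : tuple of float
        Voxel spacing (sx, sy, sz) in mm, all > 0.
    origin : tuple of float
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = field(default=AXIS_ORDER, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")
        if self.axis_order != AXIS_ORDER:
            raise ValueError(f"unsupported axis order {self.axis_order!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """Same geometry, new values."""
        return replace(self, values=np.asarray(values))

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class ROIMask:
    """Binary region of interest aligned to a reference grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    roi_name: str = "roi"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be binary, found {uniq[:5]}")
        self.values = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def check_aligned(self, grid: VolumeGrid) -> None:
        if self.shape != grid.shape:
            raise ValueError(
                f"mask {self.roi_name!r} shape {self.shape} does not match grid {grid.shape}"
            )
        if not np.allclose(self.spacing, grid.spacing) or not np.allclose(
            self.origin, grid.origin
        ):
            raise ValueError(f"mask {self.roi_name!r} geometry differs from grid")


def _target_geometry(volume_shape, spacing, origin, target_spacing):
    """New shape/origin preserving physical extent within one voxel."""
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    # extent measured between outer voxel edges
    new_shape = []
    for ax in range(3):  # z, y, x
        sp_old = spacing[2 - ax]
        sp_new = target_spacing[2 - ax]
        extent = volume_shape[ax] * sp_old
        n = max(1, int(round(extent / sp_new)))
        new_shape.append(n)
    # align the centers of the first voxels so both grids cover the same slab
    new_origin = tuple(
        origin[a] - 0.5 * spacing[a] + 0.5 * target_spacing[a] for a in range(3)
    )
    return tuple(new_shape), target_spacing, new_origin


def resample(
    volume: VolumeGrid,
    target_spacing: tuple[float, float, float],
    mode: str = "continuous",
) -> VolumeGrid:
    """Resample a volume to a new spacing.

    ``mode='continuous'`` uses trilinear interpolation, ``mode='mask'`` uses
    nearest-neighbor so binary volumes stay binary.  The physical extent of
    the grid is preserved to within one voxel.
    """
    if mode not in ("continuous", "mask"):
        raise ValueError(f"mode must be 'continuous' or 'mask', got {mode!r}")
    new_shape, new_spacing, new_origin = _target_geometry(
        volume.shape, volume.spacing, volume.origin, target_spacing
    )
    if min(new_shape) < 1:
        raise ValueError("resampling produced an empty grid")

    # map output voxel centers into input index space (per axis, z/y/x)
    coords = []
    for ax in range(3):
        a = 2 - ax  # spacing/origin are x,y,z
        phys = new_origin[a] + np.arange(new_shape[ax]) * new_spacing[a]
        idx = (phys - volume.origin[a]) / volume.spacing[a]
        coords.append(idx)
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    order = 1 if mode == "continuous" else 0
    out = ndimage.map_coordinates(
        volume.values.astype(float),
        np.stack([zz, yy, xx]),
        order=order,
        mode="nearest",
    )
    return VolumeGrid(out, new_spacing, new_origin)


def resample_mask(mask: ROIMask, target_spacing: tuple[float, float, float]) -> ROIMask:
    """Nearest-neighbor mask resampling; output is strictly binary."""
    vol = VolumeGrid(mask.values.astype(float), mask.spacing, mask.origin)
    out = resample(vol, target_spacing, mode="mask")
    return ROIMask(out.values > 0.5, out.spacing, out.origin, roi_name=mask.roi_name)
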