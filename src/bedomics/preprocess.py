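"""Physical conversions and intensity preparation for texture analysis.

Four steps sit between raw volumes and feature extraction:

* HU → relative electron density (RED) through a scanner calibration curve
  (piecewise-linear in HU, measured on phantom);
* physical dose → biologically effective dose (BED) through the
  linear-quadratic model, ``BED = D (1 + d / (α/β))`` with per-voxel
  fraction size ``d = D / n`` and α/β = 3 Gy for late-responding
  subcutaneous tissue;
* an optional spatial filter (Gaussian, Laplacian-of-Gaussian, or median);
* discretization of in-ROI intensities into a fixed number (64) of equally
  spaced bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import ROIMask, VolumeGrid

__all__ = [
    "CalibrationCurve",
    "FractionationScheme",
    "FilterSpec",
    "DiscretizedVolume",
    "hu_to_red",
    "dose_to_bed",
    "apply_filter",
    "discretize",
    "default_calibration_curve",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """HU → RED conversion table, piecewise-linear between control points.

    Beyond the endpoints the terminal segment is continued linearly and the
    result clamped at zero (a physical density cannot be negative).
    """

    hu: tuple[float, ...]
    red: tuple[float, ...]

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        red = np.asarray(self.red, dtype=float)
        if hu.size < 2:
            raise ValueError("calibration curve needs at least 2 control points")
        if hu.size != red.size:
            raise ValueError("hu and red must have equal length")
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU control points must be strictly increasing")
        if np.any(red < 0) or np.any(np.diff(red) < 0):
            raise ValueError("RED control points must be non-negative and non-decreasing")

    def __call__(self, hu_values: np.ndarray) -> np.ndarray:
        hu = np.asarray(self.hu, dtype=float)
        red = np.asarray(self.red, dtype=float)
        x = np.asarray(hu_values, dtype=float)
        out = np.interp(x, hu, red)
        # linear continuation of the terminal segments
        lo_slope = (red[1] - red[0]) / (hu[1] - hu[0])
        hi_slope = (red[-1] - red[-2]) / (hu[-1] - hu[-2])
        out = np.where(x < hu[0], red[0] + (x - hu[0]) * lo_slope, out)
        out = np.where(x > hu[-1], red[-1] + (x - hu[-1]) * hi_slope, out)
        return np.clip(out, 0.0, None)

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(tuple(df["hu"]), tuple(df["red"]))


def default_calibration_curve() -> CalibrationCurve:
    """A generic clinical HU–RED scale (air, lung, fat, water, bone)."""
    return CalibrationCurve(
        hu=(-1000.0, -500.0, -100.0, 0.0, 60.0, 1000.0),
        red=(0.001, 0.50, 0.93, 1.00, 1.05, 1.57),
    )


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription: total dose (Gy) in ``n_fractions`` equal fractions."""

    total_dose: float
    n_fractions: int
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if self.total_dose < 0:
            raise ValueError("total_dose must be non-negative")
        if self.n_fractions <= 0:
            raise ValueError("n_fractions must be a positive integer")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be positive")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions

    @property
    def prescription_bed(self) -> float:
        d = self.dose_per_fraction
        return self.total_dose * (1.0 + d / self.alpha_beta)


@dataclass(frozen=True)
class FilterSpec:
    """One of the texture pre-filters.

    kind ``gaussian``/``log``: ``scale`` is σ in mm; kind ``median``:
    ``scale`` is the kernel half-width in voxels (1 → 3×3×3); ``none`` is
    the identity.
    """

    kind: str = "none"
    scale: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "log", "median"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind != "none" and self.scale <= 0:
            raise ValueError("filter scale must be positive")


DEFAULT_FILTERS = (
    FilterSpec("none"),
    FilterSpec("gaussian", 3.0),
    FilterSpec("log", 3.0),
    FilterSpec("median", 1.0),
)


def hu_to_red(ct: VolumeGrid, curve: CalibrationCurve) -> VolumeGrid:
    """Convert a Hounsfield-unit volume to relative electron density."""
    return ct.with_values(curve(ct.values))


def dose_to_bed(dose: VolumeGrid, scheme: FractionationScheme) -> VolumeGrid:
    """Convert total physical dose to biologically effective dose.

    Per voxel with total dose ``D`` delivered in ``n`` fractions:
    ``BED = D * (1 + (D / n) / (α/β))``.
    """
    d = np.asarray(dose.values, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative everywhere")
    per_fraction = d / scheme.n_fractions
    return dose.with_values(d * (1.0 + per_fraction / scheme.alpha_beta))


def apply_filter(volume: VolumeGrid, spec: FilterSpec) -> VolumeGrid:
    """Apply a 3D filter; scales in mm are converted to voxels per axis."""
    if spec.kind == "none":
        return volume
    vals = volume.values.astype(float)
    if spec.kind in ("gaussian", "log"):
        # sigma per array axis (z, y, x); spacing is (x, y, z)
        sigma = tuple(spec.scale / volume.spacing[2 - ax] for ax in range(3))
        if spec.kind == "gaussian":
            out = ndimage.gaussian_filter(vals, sigma=sigma, mode="nearest")
        else:
            out = ndimage.gaussian_laplace(vals, sigma=sigma, mode="nearest")
    else:  # median
        size = 2 * int(round(spec.scale)) + 1
        out = ndimage.median_filter(vals, size=size, mode="nearest")
    return volume.with_values(out)


@dataclass
class DiscretizedVolume:
    """In-ROI intensities mapped to integer levels 1..n_bins.

    Levels outside the ROI are 0 (excluded).  ``intensity_range`` records
    the (min, max) used for binning.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    intensity_range: tuple[float, float]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    degenerate: bool = field(default=False)

    @property
    def in_roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(volume: VolumeGrid, mask: ROIMask, n_bins: int = 64) -> DiscretizedVolume:
    """Fixed-bin-number discretization over the in-mask intensity range.

    ``level = 1 + floor(n_bins * (x - min) / (max - min))`` with the maximum
    mapped into the top bin.  A constant ROI collapses to level 1 with a
    warning.
    """
    mask.check_aligned(volume)
    m = mask.values
    if not m.any():
        raise ValueError(f"mask {mask.roi_name!r} is empty")
    vals = volume.values[m].astype(float)
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    degenerate = hi == lo
    if degenerate:
        warnings.warn(
            f"degenerate ROI {mask.roi_name!r}: constant intensity, all voxels in bin 1",
            stacklevel=2,
        )
        levels[m] = 1
    else:
        lv = 1 + np.floor(n_bins * (volume.values[m] - lo) / (hi - lo))
        levels[m] = np.clip(lv, 1, n_bins).astype(np.int32)
    return DiscretizedVolume(
        levels=levels,
        mask=m,
        n_bins=int(n_bins),
        intensity_range=(lo, hi),
        spacing=volume.spacing,
        degenerate=degenerate,
    )
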