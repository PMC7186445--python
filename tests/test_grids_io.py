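"""Volume containers, resampling, and format round-trips."""

import warnings

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from bedomics.grids import ROIMask, VolumeGrid, resample, resample_mask
from bedomics.io import (
    rasterize_contours,
    read_ct_series,
    read_dose,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

from _oracles import point_in_polygon


# ---------------------------------------------------------------------------
# resampling


def test_resample_to_own_spacing_is_identity():
    rng = np.random.default_rng(0)
    vol = VolumeGrid(rng.normal(size=(8, 9, 10)), (1.5, 2.0, 2.5))
    out = resample(vol, vol.spacing)
    assert out.shape == vol.shape
    np.testing.assert_allclose(out.values, vol.values, atol=1e-12)


def test_resample_constant_volume_stays_constant():
    vol = VolumeGrid(np.full((6, 6, 6), 3.7), (1.0, 1.0, 1.0))
    out = resample(vol, (2.3, 1.7, 0.9))
    np.testing.assert_allclose(out.values, 3.7, atol=1e-12)


def test_resample_linear_ramp_exact_in_interior():
    # trilinear interpolation reproduces a linear field exactly
    nz = 30
    vals = np.broadcast_to(np.arange(nz, dtype=float)[:, None, None], (nz, 4, 4)).copy()
    vol = VolumeGrid(vals, (1.0, 1.0, 1.0))
    out = resample(vol, (1.0, 1.0, 3.0))
    z_phys = out.origin[2] + np.arange(out.shape[0]) * 3.0
    interior = (z_phys >= 1.0) & (z_phys <= nz - 2.0)
    np.testing.assert_allclose(out.values[interior, 2, 2], z_phys[interior], atol=1e-9)


def test_resample_preserves_physical_extent():
    vol = VolumeGrid(np.zeros((10, 20, 30)), (0.977, 0.977, 5.0))
    out = resample(vol, (3.0, 3.0, 3.0))
    for ax in range(3):
        old = vol.shape[ax] * vol.spacing[2 - ax]
        new = out.shape[ax] * out.spacing[2 - ax]
        assert abs(old - new) <= max(vol.spacing[2 - ax], out.spacing[2 - ax])


def test_mask_resampling_stays_binary():
    rng = np.random.default_rng(1)
    mask = ROIMask(rng.uniform(size=(9, 9, 9)) > 0.5, (2.0, 2.0, 2.0), roi_name="m")
    out = resample_mask(mask, (1.3, 1.3, 1.3))
    assert out.values.dtype == bool
    assert set(np.unique(out.values.astype(int))) <= {0, 1}


def test_volume_rejects_nonfinite_and_bad_spacing():
    with pytest.raises(ValueError):
        VolumeGrid(np.array([[[np.nan]]]), (1, 1, 1))
    with pytest.raises(ValueError):
        VolumeGrid(np.zeros((2, 2, 2)), (1, 0, 1))


# ---------------------------------------------------------------------------
# DICOM fixtures (written in-memory by the test)


def _ct_slice(tmp_path, name, z, rows=16, cols=16, value=1024, series_uid=None,
              pixel_spacing=(0.977, 0.977)):
    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    fm.MediaStorageSOPInstanceUID = generate_uid()
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(tmp_path / name), {}, file_meta=fm, preamble=b"\x00" * 128)
    ds.Modality = "CT"
    ds.SeriesInstanceUID = series_uid or "1.2.3.4"
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = list(pixel_spacing)
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.SliceThickness = 5.0
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    arr = np.full((rows, cols), value, dtype=np.uint16)
    ds.PixelData = arr.tobytes()
    ds.save_as(tmp_path / name, enforce_file_format=True)


def test_read_ct_series_rescale_sorting_and_spacing(tmp_path):
    # write slices in shuffled file order; z positions 0, 5, 10 mm
    for name, z in [("b.dcm", 5), ("c.dcm", 10), ("a.dcm", 0)]:
        _ct_slice(tmp_path, name, z)
    vol = read_ct_series(tmp_path)
    # slope 1, intercept -1024, stored 1024 → HU 0
    np.testing.assert_allclose(vol.values, 0.0)
    assert vol.spacing == (0.977, 0.977, 5.0)
    assert vol.shape == (3, 16, 16)


def test_read_ct_series_order_invariance(tmp_path):
    d1, d2 = tmp_path / "sorted", tmp_path / "shuffled"
    d1.mkdir(), d2.mkdir()
    for i, z in enumerate([0, 5, 10]):
        _ct_slice(d1, f"s{i}.dcm", z, value=1000 + 10 * i)
    for name, (i, z) in zip(["x.dcm", "a.dcm", "m.dcm"], enumerate([0, 5, 10])):
        _ct_slice(d2, name, z, value=1000 + 10 * i)
    v1, v2 = read_ct_series(d1), read_ct_series(d2)
    np.testing.assert_array_equal(v1.values, v2.values)


def test_read_ct_series_rejects_mixed_series(tmp_path):
    _ct_slice(tmp_path, "a.dcm", 0, series_uid="1.1")
    _ct_slice(tmp_path, "b.dcm", 5, series_uid="2.2")
    with pytest.raises(ValueError, match="series"):
        read_ct_series(tmp_path)


def _dose_file(path, stored, scaling=0.01, spacing=2.5):
    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    fm.MediaStorageSOPInstanceUID = generate_uid()
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=fm, preamble=b"\x00" * 128)
    ds.Modality = "RTDOSE"
    stored = np.asarray(stored, dtype=np.uint32)
    ds.NumberOfFrames = stored.shape[0]
    ds.Rows, ds.Columns = stored.shape[1], stored.shape[2]
    ds.PixelSpacing = [spacing, spacing]
    ds.GridFrameOffsetVector = [i * spacing for i in range(stored.shape[0])]
    ds.ImagePositionPatient = [0.0, 0.0, 0.0]
    if scaling is not None:
        ds.DoseGridScaling = scaling
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def test_read_dose_scaling_and_spacing(tmp_path):
    path = tmp_path / "dose.dcm"
    _dose_file(path, np.full((4, 8, 8), 4000), scaling=0.01)
    dose = read_dose(path)
    np.testing.assert_allclose(dose.values, 40.0)
    assert dose.spacing == (2.5, 2.5, 2.5)


def test_read_dose_zero_array_and_missing_scaling(tmp_path):
    p0 = tmp_path / "zero.dcm"
    _dose_file(p0, np.zeros((2, 4, 4)))
    np.testing.assert_allclose(read_dose(p0).values, 0.0)
    p1 = tmp_path / "noscale.dcm"
    _dose_file(p1, np.zeros((2, 4, 4)), scaling=None)
    with pytest.raises(ValueError, match="DoseGridScaling"):
        read_dose(p1)


# ---------------------------------------------------------------------------
# contour rasterization


def test_square_polygon_voxel_count():
    ref = VolumeGrid(np.zeros((3, 40, 40)), (1.0, 1.0, 1.0))
    square = [(4.5, 4.5), (24.5, 4.5), (24.5, 24.5), (4.5, 24.5)]
    mask = rasterize_contours([(1.0, square)], ref)
    assert mask.values[1].sum() == 400
    assert mask.values[0].sum() == 0 and mask.values[2].sum() == 0


def test_polygon_orientation_invariance():
    ref = VolumeGrid(np.zeros((1, 30, 30)), (1.0, 1.0, 1.0))
    poly = [(3.2, 4.1), (20.3, 5.2), (18.7, 22.0), (5.0, 19.5)]
    m1 = rasterize_contours([(0.0, poly)], ref)
    m2 = rasterize_contours([(0.0, poly[::-1])], ref)
    np.testing.assert_array_equal(m1.values, m2.values)


def test_star_polygon_matches_even_odd_oracle():
    rng = np.random.default_rng(7)
    # star-shaped polygon around (15, 15)
    angles = np.sort(rng.uniform(0, 2 * np.pi, 11))
    radii = rng.uniform(4, 13, len(angles))
    poly = [(15 + r * np.cos(a), 15 + r * np.sin(a)) for r, a in zip(radii, angles)]
    ref = VolumeGrid(np.zeros((1, 30, 30)), (1.0, 1.0, 1.0))
    mask = rasterize_contours([(0.0, poly)], ref)
    oracle = np.zeros((30, 30), dtype=bool)
    for y in range(30):
        for x in range(30):
            oracle[y, x] = point_in_polygon(float(x), float(y), poly)
    # agreement within one voxel-row of boundary voxels
    assert abs(int(mask.values[0].sum()) - int(oracle.sum())) <= 30


def test_polygon_outside_grid_is_skipped_with_warning():
    ref = VolumeGrid(np.zeros((2, 10, 10)), (1.0, 1.0, 1.0))
    with pytest.warns(UserWarning, match="outside the grid"):
        mask = rasterize_contours([(50.0, [(1, 1), (5, 1), (5, 5)])], ref)
    assert mask.voxel_count == 0


def test_rasterized_convex_roi_volume_close_to_slab_volume():
    # cylinder of radius 12 mm over 10 slices of 2 mm on a 1 mm grid
    ref = VolumeGrid(np.zeros((10, 40, 40)), (1.0, 1.0, 2.0))
    theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    circle = [(20 + 12 * np.cos(t), 20 + 12 * np.sin(t)) for t in theta]
    mask = rasterize_contours([(z * 2.0, circle) for z in range(10)], ref)
    assert mask.voxel_count >= 1000
    vol_mask = mask.voxel_count * np.prod(ref.spacing)
    vol_true = np.pi * 12**2 * 10 * 2.0
    assert abs(vol_mask - vol_true) / vol_true < 0.10
    out = resample_mask(mask, (3.0, 3.0, 3.0))
    vol_res = out.voxel_count * 27.0
    assert abs(vol_res - vol_true) / vol_true < 0.10


# ---------------------------------------------------------------------------
# research volume round-trips


@pytest.mark.parametrize("ext", [".nii.gz", ".nrrd"])
def test_volume_round_trip(tmp_path, ext):
    rng = np.random.default_rng(3)
    vol = VolumeGrid(rng.normal(size=(5, 6, 7)), (0.977, 0.977, 5.0), (1.0, -2.0, 3.0))
    path = tmp_path / f"v{ext}"
    write_volume(vol, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.values, vol.values)
    np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)
    np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)


def test_mask_round_trip_preserves_binary(tmp_path):
    rng = np.random.default_rng(4)
    mask = ROIMask(rng.uniform(size=(4, 5, 6)) > 0.4, (1, 1, 1), roi_name="ptv")
    path = tmp_path / "m.nii.gz"
    write_mask(mask, path)
    back = read_mask(path, roi_name="ptv")
    np.testing.assert_array_equal(back.values, mask.values)


def test_unknown_extension_rejected(tmp_path):
    vol = VolumeGrid(np.zeros((2, 2, 2)), (1, 1, 1))
    with pytest.raises(ValueError, match="supported"):
        write_volume(vol, tmp_path / "vol.xyz")
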