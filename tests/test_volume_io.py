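"""Volume I/O, SUV conversion, and resampling."""

import nibabel as nib
import numpy as np
import pytest

from petleskit import (
    PETMeta,
    VolumeGrid,
    read_volume,
    resample_to,
    to_suv,
    write_volume,
)
from petleskit.errors import FormatError, GeometryError, MetadataError, ValidationError
from petleskit.io import read_pet_meta, suv_to_activity


def test_write_read_round_trip(tmp_path, rng):
    grid = VolumeGrid(rng.random((8, 9, 10)).astype(np.float32),
                      spacing=(1.5, 2.0, 3.27), origin=(-10.0, 5.0, 2.5))
    back = read_volume(write_volume(grid, tmp_path / "v.nii.gz"), "pet")
    np.testing.assert_array_equal(back.data, grid.data)
    assert np.allclose(back.spacing, grid.spacing, atol=1e-3)
    assert np.allclose(back.origin, grid.origin, atol=1e-3)


def test_read_rejects_4d(tmp_path):
    img = nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4))
    nib.save(img, str(tmp_path / "v4.nii.gz"))
    with pytest.raises(FormatError):
        read_volume(tmp_path / "v4.nii.gz", "pet")


def test_read_mask_rejects_fractional(tmp_path):
    img = nib.Nifti1Image(np.full((4, 4, 4), 0.5, dtype=np.float32), np.eye(4))
    nib.save(img, str(tmp_path / "m.nii.gz"))
    with pytest.raises(ValidationError):
        read_volume(tmp_path / "m.nii.gz", "mask")


def test_phantom_mask_round_trip(tmp_path, small_scan):
    path = write_volume(small_scan.gt_mask, tmp_path / "gt.nii.gz")
    back = read_volume(path, "mask")
    assert back.data.dtype.kind == "i"
    np.testing.assert_array_equal(back.data, small_scan.gt_mask.data)
    assert np.allclose(back.spacing, small_scan.gt_mask.spacing, atol=1e-3)


def test_suv_direct_arithmetic():
    pet = VolumeGrid(np.full((2, 2, 2), 5000.0), spacing=(1, 1, 1))
    meta = PETMeta(injected_dose_bq=185e6, body_weight_kg=74.0)
    suv = to_suv(pet, meta)
    np.testing.assert_allclose(suv.data, 2.0)


def test_suv_zero_and_negative_clipping():
    pet = VolumeGrid(np.array([[[0.0, -3.0]]]), spacing=(1, 1, 1))
    suv = to_suv(pet, PETMeta(1e8, 70.0))
    np.testing.assert_array_equal(suv.data, 0.0)


def test_suv_linearity(rng):
    act = rng.random((6, 6, 6)) * 1e4
    pet = VolumeGrid(act, spacing=(2, 2, 2))
    s1 = to_suv(pet, PETMeta(2e8, 80.0))
    s2 = to_suv(pet.like(act * 2), PETMeta(2e8, 80.0))
    s3 = to_suv(pet, PETMeta(4e8, 80.0))
    np.testing.assert_allclose(s2.data, 2 * s1.data)
    np.testing.assert_allclose(s3.data, s1.data / 2)


def test_suv_round_trip_through_activity(small_scan):
    meta = PETMeta(injected_dose_bq=195.36e6, body_weight_kg=81.0)
    act = suv_to_activity(small_scan.pet, meta)
    back = to_suv(act, meta)
    np.testing.assert_allclose(back.data, np.clip(small_scan.pet.data, 0, None), atol=1e-6)


def test_missing_metadata_errors():
    with pytest.raises(MetadataError):
        PETMeta(injected_dose_bq=0, body_weight_kg=70)
    with pytest.raises(MetadataError):
        PETMeta(injected_dose_bq=1e8, body_weight_kg=-1)


def test_read_pet_meta_mbq_conversion(tmp_path):
    p = tmp_path / "meta.json"
    p.write_text('{"injected_dose_mbq": 195.36, "body_weight_kg": 81}')
    meta = read_pet_meta(p)
    assert meta.injected_dose_bq == pytest.approx(195.36e6)


def test_resample_identity(small_scan):
    out = resample_to(small_scan.pet, small_scan.gt_mask, role="mask")
    np.testing.assert_array_equal(out.data, small_scan.gt_mask.data)


def test_resample_mask_preserves_value_set(small_scan):
    mask = small_scan.gt_mask
    coarse = VolumeGrid(
        np.asarray(mask.data)[::2, ::2, ::2],
        spacing=tuple(2 * s for s in mask.spacing),
        origin=mask.origin,
    )
    out = resample_to(mask, coarse, role="mask")
    assert set(np.unique(out.data)) <= {0, 1}


def test_resample_no_overlap_errors(small_scan):
    far = VolumeGrid(np.zeros((4, 4, 4)), spacing=(1, 1, 1), origin=(1e5, 1e5, 1e5))
    with pytest.raises(GeometryError):
        resample_to(small_scan.pet, far, role="ct")


def test_downsample_then_restore_dsc():
    """A mask held on a 2x-thicker-slice grid and resampled back onto the
    PET grid recovers every lesion >= 1 cm^3 with DSC >= 0.9."""
    from petleskit import PhantomSpec, connected_components, generate_scan
    from petleskit.phantom import LesionSpec

    spec = PhantomSpec(
        shape=(96, 96, 128), spacing=(1.5, 1.5, 1.5),
        lesions=[LesionSpec((48, 48, 30), 6.5, 20.0),
                 LesionSpec((48, 48, 60), 10.0, 20.0),
                 LesionSpec((48, 48, 95), 15.0, 20.0)],
        seed=0,
    )
    mask = generate_scan(spec).gt_mask
    nx, ny, nz = mask.shape
    coarse_ref = VolumeGrid(
        np.zeros((nx, ny, nz // 2)),
        spacing=(1.5, 1.5, 3.0),
        origin=tuple(np.add(mask.origin, (0, 0, 0.75))),
    )
    down = resample_to(coarse_ref, mask, role="mask")
    restored = resample_to(mask, down, role="mask")

    from scipy import ndimage

    labels, sizes = connected_components(mask)
    lab = np.asarray(labels.data)
    voxvol = mask.voxel_volume_mm3 * 1e-3
    rest = np.asarray(restored.data) > 0
    checked = 0
    for k in range(1, len(sizes) + 1):
        assert sizes[k - 1] * voxvol >= 1.0
        sel = lab == k
        # lesions are spatially separated, so the restored voxels in a small
        # neighbourhood of this lesion belong to it
        local = rest & ndimage.binary_dilation(sel, iterations=2)
        dsc = 2 * (sel & local).sum() / (sel.sum() + local.sum())
        checked += 1
        assert dsc >= 0.9
    assert checked >= 1
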