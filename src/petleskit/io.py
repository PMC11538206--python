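"""NIfTI I/O, SUV conversion, and resampling onto the PET grid.

Volumes are read with nibabel, reoriented to closest-canonical (RAS), and
required to have an axis-aligned affine so that geometry reduces to spacing
plus origin. Companion volumes (CT, masks, organ label maps) are resampled
onto the PET grid with trilinear interpolation for continuous images and
nearest-neighbour for masks/labels, via ``scipy.ndimage.map_coordinates``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, GeometryError, MetadataError, ValidationError
from .grid import PETMeta, VolumeGrid

ROLES = ("pet", "ct", "mask", "labels")
_INT_ROLES = ("mask", "labels")
_MASK_INT_TOL = 1e-6
# off-diagonal tolerance (mm per voxel) when requiring an axis-aligned affine
_OBLIQUE_TOL = 1e-3


def _grid_from_nifti(img: nib.Nifti1Image) -> VolumeGrid:
    img = nib.as_closest_canonical(img)
    aff = img.affine
    rot = aff[:3, :3]
    diag = np.diag(rot)
    off = rot - np.diag(diag)
    if np.max(np.abs(off)) > _OBLIQUE_TOL:
        raise FormatError(
            "oblique/rotated affines are not supported; resample the volume "
            "to an axis-aligned grid first"
        )
    if np.any(diag <= 0):
        raise FormatError(f"non-positive voxel scaling in canonical affine: {diag}")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got {data.ndim}D")
    return VolumeGrid(np.asarray(data), tuple(diag), tuple(aff[:3, 3]))


def read_volume(path: str | Path, expected_role: str = "pet") -> VolumeGrid:
    """Read a 3D NIfTI volume and validate it for its role.

    Parameters
    ----------
    path
        ``.nii`` / ``.nii.gz`` file.
    expected_role
        One of ``pet``, ``ct``, ``mask``, ``labels``. Mask/label volumes are
        validated to hold non-negative integers (within 1e-6) and returned
        with an integer dtype.
    """
    if expected_role not in ROLES:
        raise ValueError(f"expected_role must be one of {ROLES}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    grid = _grid_from_nifti(img)
    if expected_role in _INT_ROLES:
        data = np.asarray(grid.data, dtype=np.float64)
        rounded = np.round(data)
        if np.max(np.abs(data - rounded), initial=0.0) > _MASK_INT_TOL:
            raise ValidationError(f"{expected_role} volume has fractional values")
        if rounded.min(initial=0.0) < 0:
            raise ValidationError(f"{expected_role} volume has negative values")
        grid = grid.like(rounded.astype(np.int32))
    return grid


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a VolumeGrid as NIfTI-1, preserving spacing and origin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = grid.data
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
    elif data.dtype.kind in "iub":
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    return path


def read_pet_meta(path: str | Path) -> PETMeta:
    """Read PET metadata from a JSON sidecar.

    Accepted keys: ``injected_dose_bq`` or ``injected_dose_mbq`` (converted),
    ``body_weight_kg``, optional ``units`` (``BQML``/``SUV``).
    """
    with open(path) as fh:
        raw = json.load(fh)
    dose = raw.get("injected_dose_bq")
    if dose is None and "injected_dose_mbq" in raw:
        dose = float(raw["injected_dose_mbq"]) * 1e6
    if dose is None:
        raise MetadataError(f"no injected dose in {path}")
    weight = raw.get("body_weight_kg")
    if weight is None:
        raise MetadataError(f"no body weight in {path}")
    return PETMeta(float(dose), float(weight), raw.get("units", "BQML"))


def to_suv(pet: VolumeGrid, meta: PETMeta) -> VolumeGrid:
    """Convert an activity-concentration PET volume to body-weight SUV.

    SUV_bw(v) = activity(v) [Bq/mL] * body_weight [g] / injected_dose [Bq].
    Small negative reconstruction noise is clipped to zero first. If the
    volume is already in SUV units it is returned unchanged (clipped).
    """
    act = np.clip(np.asarray(pet.data, dtype=np.float64), 0.0, None)
    if meta.units_in == "SUV":
        return pet.like(act)
    suv = act * (meta.body_weight_kg * 1000.0) / meta.injected_dose_bq
    return pet.like(suv)


def suv_to_activity(pet_suv: VolumeGrid, meta: PETMeta) -> VolumeGrid:
    """Inverse of :func:`to_suv`: SUV back to activity concentration (Bq/mL)."""
    suv = np.asarray(pet_suv.data, dtype=np.float64)
    act = suv * meta.injected_dose_bq / (meta.body_weight_kg * 1000.0)
    return pet_suv.like(act)


def resample_to(reference: VolumeGrid, moving: VolumeGrid, role: str = "mask") -> VolumeGrid:
    """Resample ``moving`` onto the grid of ``reference``.

    CT (and PET) use trilinear interpolation; masks and label maps use
    nearest-neighbour so the value set is preserved exactly. Voxels of the
    reference grid falling outside ``moving`` get 0 (masks/labels/pet) or
    -1000 HU (ct).

    Raises
    ------
    GeometryError
        If the two volumes share no physical overlap.
    """
    if role not in ("ct", "pet", "mask", "labels"):
        raise ValueError(f"unsupported role {role!r}")
    lo_r, hi_r = reference.physical_extent()
    lo_m, hi_m = moving.physical_extent()
    if np.any(hi_r <= lo_m) or np.any(hi_m <= lo_r):
        raise GeometryError("volumes share no spatial overlap")
    if moving.aligned_with(reference):
        return reference.like(moving.data.copy())

    # continuous voxel coordinates of the reference grid inside `moving`
    idx = np.indices(reference.shape, dtype=np.float64)
    coords = [
        (reference.origin[a] + reference.spacing[a] * idx[a] - moving.origin[a])
        / moving.spacing[a]
        for a in range(3)
    ]
    order = 0 if role in _INT_ROLES else 1
    cval = -1000.0 if role == "ct" else 0.0
    out = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=np.float64),
        coords,
        order=order,
        mode="constant",
        cval=cval,
    )
    if role in _INT_ROLES:
        out = np.round(out).astype(np.int32)
    return reference.like(out)
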