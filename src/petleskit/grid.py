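"""Volume geometry: the shared grid contract for PET, CT, masks and label maps.

Every volume in the toolkit is a :class:`VolumeGrid` - a 3D scalar array with
voxel spacing and physical origin in millimetres, axes ordered (x, y, z) in
RAS orientation. Cross-volume operations (overlap metrics, burden over a
mask, region assignment) require *alignment*: identical shape plus spacing
and origin agreeing within ``ALIGN_TOL_MM``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, MetadataError

ALIGN_TOL_MM = 1e-3


@dataclass
class VolumeGrid:
    """A 3D scalar field with physical geometry.

    Parameters
    ----------
    data
        3D array; SUV for PET, HU for CT, non-negative integers for masks
        and label maps.
    spacing
        Voxel size ``(Sx, Sy, Sz)`` in mm, strictly positive.
    origin
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise GeometryError("origin must have 3 components")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def affine(self) -> np.ndarray:
        """Axis-aligned RAS affine mapping voxel indices to mm."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def aligned_with(self, other: "VolumeGrid", tol: float = ALIGN_TOL_MM) -> bool:
        """True iff shapes match and spacing/origin agree within ``tol`` mm."""
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def require_alignment(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.aligned_with(other):
            raise GeometryError(
                f"{what} are not aligned: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different data."""
        return VolumeGrid(np.asarray(data), self.spacing, self.origin)

    def physical_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) corners of the volume in mm (voxel-edge to voxel-edge)."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class PETMeta:
    """PET acquisition metadata needed for SUV normalization.

    ``injected_dose_bq`` is assumed decay-corrected to the scan reference
    time (the DICOM convention); no decay bookkeeping is done here.
    """

    injected_dose_bq: float
    body_weight_kg: float
    units_in: str = "BQML"  # "BQML" (activity concentration) or "SUV"

    VALID_UNITS = ("BQML", "SUV")

    def __post_init__(self) -> None:
        if self.injected_dose_bq is None or not self.injected_dose_bq > 0:
            raise MetadataError(f"injected dose must be > 0, got {self.injected_dose_bq}")
        if self.body_weight_kg is None or not self.body_weight_kg > 0:
            raise MetadataError(f"body weight must be > 0, got {self.body_weight_kg}")
        self.units_in = str(self.units_in).upper()
        if self.units_in not in self.VALID_UNITS:
            raise MetadataError(f"units_in must be one of {self.VALID_UNITS}")
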