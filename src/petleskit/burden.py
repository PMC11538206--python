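"""Tumor-burden quantification over a binary mask on a PET volume.

For a mask M on an SUV volume with voxel spacing (Sx, Sy, Sz) in mm:

    SUVmax  = max(SUV[M > 0])
    SUVmean = mean(SUV[M > 0])
    TTV     = sum(M > 0) * Sx * Sy * Sz * 0.001        [cm^3]
    TLU     = SUVmean * TTV                            [SUV * cm^3]

TLU weights tumor volume by mean receptor-expression intensity and is the
scan-level burden tracked across therapy. Per-lesion rows use the same
26-connected lesion definition as detection scoring. An empty mask yields
TTV = TLU = 0 with SUVmax/SUVmean undefined (NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .lesion_eval import connected_components

PER_LESION_COLUMNS = ["lesion_id", "n_voxels", "suvmax", "suvmean", "ttv_cm3", "tlu"]


@dataclass
class BurdenReport:
    """Scan-level burden plus one row per 26-connected lesion."""

    suvmax: float        # NaN when the mask is empty
    suvmean: float       # NaN when the mask is empty
    ttv_cm3: float
    tlu: float           # SUV * cm^3 (conventionally printed as [cm^3])
    n_lesions: int
    per_lesion: pd.DataFrame

    @property
    def defined(self) -> bool:
        return self.n_lesions > 0


def scan_burden(pet: VolumeGrid, mask: VolumeGrid, connectivity: int = 26) -> BurdenReport:
    """Burden metrics of one binary mask over an SUV volume."""
    pet.require_alignment(mask, "pet and mask")
    suv = np.asarray(pet.data, dtype=np.float64)
    m = np.asarray(mask.data) > 0
    voxvol_cm3 = mask.voxel_volume_mm3 * 1e-3

    labels, sizes = connected_components(mask.like(m.astype(np.int32)), connectivity)
    lab = np.asarray(labels.data)
    rows = []
    for k in range(1, len(sizes) + 1):
        vals = suv[lab == k]
        ttv = float(sizes[k - 1]) * voxvol_cm3
        mean = float(vals.mean())
        rows.append({
            "lesion_id": k,
            "n_voxels": int(sizes[k - 1]),
            "suvmax": float(vals.max()),
            "suvmean": mean,
            "ttv_cm3": ttv,
            "tlu": mean * ttv,
        })
    per_lesion = pd.DataFrame(rows, columns=PER_LESION_COLUMNS)

    if m.any():
        vals = suv[m]
        suvmax = float(vals.max())
        suvmean = float(vals.mean())
        ttv = float(m.sum()) * voxvol_cm3
        tlu = suvmean * ttv
    else:
        suvmax = suvmean = float("nan")
        ttv = tlu = 0.0
    return BurdenReport(
        suvmax=suvmax,
        suvmean=suvmean,
        ttv_cm3=ttv,
        tlu=tlu,
        n_lesions=len(sizes),
        per_lesion=per_lesion,
    )


def paired_burden(
    pet: VolumeGrid, gt: VolumeGrid, pred: VolumeGrid, connectivity: int = 26
) -> tuple[BurdenReport, BurdenReport]:
    """Burden of the ground-truth and predicted masks over the same PET.

    Row order within each report is the deterministic component order, so
    paired scan-level values feed agreement statistics directly.
    """
    return (
        scan_burden(pet, gt, connectivity),
        scan_burden(pet, pred, connectivity),
    )
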