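"""Anatomically resolved failure analysis.

Every evaluated lesion (TP, FN over ground-truth components; FP over
predicted components) is assigned to the anatomical region covering the
plurality of its voxels in an integer organ label map, region frequencies
are tabulated per status, and liver lesions get a tumor-to-background
ratio (TBR): lesion SUVmax over the normal-liver SUVmean, where "normal
liver" is the liver label minus every lesion voxel (ground truth and
prediction), since an organ label map does not exclude tumors itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .grid import VolumeGrid
from .phantom import ORGAN_CODES, ORGAN_NAMES

LEDGER_COLUMNS = [
    "scan_id", "cluster_id", "lesion_uid", "status", "region",
    "suvmax", "suvmean", "ttv_cm3", "tlu", "tbr",
]
STATUSES = ("TP", "FN", "FP")


def assign_regions(
    lesion_labels: VolumeGrid, organ_labels: VolumeGrid
) -> dict[int, str]:
    """Region name per lesion label by plurality vote over its voxels.

    Ties break toward the smaller organ code; a lesion whose plurality is
    background maps to ``"unassigned"``. Deterministic and total: every
    lesion receives exactly one region.
    """
    lesion_labels.require_alignment(organ_labels, "lesions and organ labels")
    les = np.asarray(lesion_labels.data)
    org = np.asarray(organ_labels.data)
    out: dict[int, str] = {}
    ids = np.unique(les)
    ids = ids[ids > 0]
    n_org = int(org.max()) + 1
    for k in ids:
        codes = org[les == k]
        counts = np.bincount(codes, minlength=n_org)
        best = int(np.argmax(counts))  # argmax ties break toward smaller code
        out[int(k)] = "unassigned" if best == 0 else ORGAN_NAMES.get(best, "unassigned")
    return out


def region_frequency(ledger: pd.DataFrame) -> pd.DataFrame:
    """Region x status contingency table of lesion counts.

    Rows are regions, columns TP/FN/FP; margins are consistent with the
    cohort totals by construction (every ledger row counted once).
    """
    if ledger.empty:
        raise ParameterError("ledger is empty")
    tab = (
        ledger.groupby(["region", "status"]).size().unstack(fill_value=0)
    )
    for s in STATUSES:
        if s not in tab.columns:
            tab[s] = 0
    return tab[list(STATUSES)]


def liver_tbr(
    pet: VolumeGrid,
    lesion_mask: VolumeGrid,
    organ_labels: VolumeGrid,
    lesion_suvmax: pd.Series | dict | None = None,
) -> tuple[float, float]:
    """Normal-liver SUVmean for TBR computation.

    Returns ``(liver_suvmean, n_liver_voxels_used)``. The mean is taken
    over liver-label voxels excluding every voxel of ``lesion_mask`` (pass
    the union of ground-truth and predicted masks so tumor uptake cannot
    inflate the background).

    Raises
    ------
    GeometryError
        If volumes are misaligned.
    ParameterError
        If the label map has no liver voxels (TBR undefined for such scans).
    """
    pet.require_alignment(organ_labels, "pet and organ labels")
    pet.require_alignment(lesion_mask, "pet and lesion mask")
    org = np.asarray(organ_labels.data)
    liver = org == ORGAN_CODES["liver"]
    if not liver.any():
        raise ParameterError("no liver label present; TBR undefined")
    normal = liver & ~(np.asarray(lesion_mask.data) > 0)
    if not normal.any():
        raise ParameterError("liver entirely covered by lesions; TBR undefined")
    suvmean = float(np.asarray(pet.data, dtype=np.float64)[normal].mean())
    return suvmean, int(normal.sum())


def tbr_for_lesions(suvmax: np.ndarray | pd.Series, liver_suvmean: float) -> np.ndarray:
    """TBR = lesion SUVmax / normal-liver SUVmean."""
    if not liver_suvmean > 0:
        raise ParameterError("liver SUVmean must be positive")
    return np.asarray(suvmax, dtype=float) / liver_suvmean


def build_ledger(
    scan_id: str,
    cluster_id: str,
    pet: VolumeGrid,
    gt_labels: VolumeGrid,
    pred_labels: VolumeGrid,
    gt_lesions: pd.DataFrame,
    pred_components: pd.DataFrame,
    organ_labels: VolumeGrid | None,
) -> pd.DataFrame:
    """One ledger row per evaluated lesion of one scan.

    TP and FN rows are measured over ground-truth component voxels, FP rows
    over predicted component voxels (each status has exactly one natural
    support). TBR is filled for liver lesions when a liver label exists.
    """
    suv = np.asarray(pet.data, dtype=np.float64)
    voxvol_cm3 = pet.voxel_volume_mm3 * 1e-3
    regions_gt = assign_regions(gt_labels, organ_labels) if organ_labels is not None else {}
    regions_pr = assign_regions(pred_labels, organ_labels) if organ_labels is not None else {}

    liver_mean = None
    if organ_labels is not None and (np.asarray(organ_labels.data) == ORGAN_CODES["liver"]).any():
        union = pet.like(
            ((np.asarray(gt_labels.data) > 0) | (np.asarray(pred_labels.data) > 0)).astype(np.int32)
        )
        try:
            liver_mean, _ = liver_tbr(pet, union, organ_labels)
        except ParameterError:
            liver_mean = None

    rows = []
    gl = np.asarray(gt_labels.data)
    pl = np.asarray(pred_labels.data)
    for row in gt_lesions.itertuples(index=False):
        vals = suv[gl == row.id]
        region = regions_gt.get(int(row.id), "unassigned")
        mean = float(vals.mean()) if len(vals) else float("nan")
        ttv = float(len(vals)) * voxvol_cm3
        smax = float(vals.max()) if len(vals) else float("nan")
        rows.append({
            "scan_id": scan_id, "cluster_id": cluster_id,
            "lesion_uid": f"{scan_id}:gt{row.id}", "status": row.status,
            "region": region, "suvmax": smax, "suvmean": mean,
            "ttv_cm3": ttv, "tlu": mean * ttv,
            "tbr": (smax / liver_mean) if (liver_mean and region == "liver") else float("nan"),
        })
    for row in pred_components.itertuples(index=False):
        if row.status != "FP":
            continue
        vals = suv[pl == row.id]
        region = regions_pr.get(int(row.id), "unassigned")
        mean = float(vals.mean()) if len(vals) else float("nan")
        ttv = float(len(vals)) * voxvol_cm3
        smax = float(vals.max()) if len(vals) else float("nan")
        rows.append({
            "scan_id": scan_id, "cluster_id": cluster_id,
            "lesion_uid": f"{scan_id}:fp{row.id}", "status": "FP",
            "region": region, "suvmax": smax, "suvmean": mean,
            "ttv_cm3": ttv, "tlu": mean * ttv,
            "tbr": (smax / liver_mean) if (liver_mean and region == "liver") else float("nan"),
        })
    return pd.DataFrame(rows, columns=LEDGER_COLUMNS)
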