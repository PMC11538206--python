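"""Scan-level and lesion-level detection scoring.

A scan is classed TP/TN/FP/FN from whether ground truth and prediction are
each empty or not. Lesion-level scoring decomposes both masks into
26-connected components: a ground-truth lesion is detected (TP) iff it
shares at least one voxel with the prediction (the overlap fraction is
configurable), otherwise FN; every predicted component with zero
ground-truth overlap counts as one false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, ParameterError, ValidationError
from .grid import VolumeGrid

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(
    mask: VolumeGrid, connectivity: int = 26
) -> tuple[VolumeGrid, np.ndarray]:
    """Label the maximal connected components of a binary mask.

    Labels are assigned 1..K deterministically in ascending order of each
    component's first voxel in lexicographic (C-order) index order.

    Returns
    -------
    (labels, sizes)
        ``labels`` is an int VolumeGrid; ``sizes[k-1]`` is the voxel count
        of component ``k``.
    """
    if connectivity not in _STRUCTS:
        raise ParameterError(f"connectivity must be one of {tuple(_STRUCTS)}")
    data = np.asarray(mask.data)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"mask must be binary, found values {vals[:10]}")
    lab, n = ndimage.label(data, structure=_STRUCTS[connectivity])
    if n > 0:
        flat = lab.ravel()
        nz = np.flatnonzero(flat)
        # first occurrence of each label in C order -> deterministic relabel
        first = np.full(n + 1, flat.size, dtype=np.int64)
        # reversed so earlier indices overwrite later ones
        first[flat[nz[::-1]]] = nz[::-1]
        order = np.argsort(first[1:], kind="stable")  # old labels sorted by first voxel
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[1 + order] = np.arange(1, n + 1)
        lab = remap[lab]
        sizes = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    else:
        sizes = np.zeros(0, dtype=np.int64)
    return mask.like(lab.astype(np.int32)), sizes


@dataclass
class MatchResult:
    """Per-scan outcome of matching a prediction against ground truth."""

    scan_id: str
    scan_class: str  # TP | TN | FP | FN (scan level)
    dsc: float
    n_gt_voxels: int
    n_pred_voxels: int
    n_overlap_voxels: int
    gt_lesions: pd.DataFrame      # id, n_voxels, overlap_voxels, status (TP/FN)
    pred_components: pd.DataFrame  # id, n_voxels, overlap_voxels, status
    n_tp: int
    n_fn: int
    n_fp: int

    @property
    def per_scan_sensitivity(self) -> float | None:
        """Percent of GT lesions detected; None when the scan has no GT lesion."""
        n = self.n_tp + self.n_fn
        return 100.0 * self.n_tp / n if n else None


def evaluate_scan(
    gt: VolumeGrid,
    pred: VolumeGrid,
    scan_id: str = "",
    connectivity: int = 26,
    min_overlap_frac: float = 0.0,
) -> MatchResult:
    """Score one predicted mask against its ground truth.

    A GT lesion counts as TP when the overlapping fraction of its voxels
    exceeds ``min_overlap_frac`` (default: any shared voxel). A predicted
    component sharing no voxel with the ground truth is one FP.
    """
    gt.require_alignment(pred, "gt and pred")
    gt_lab, gt_sizes = connected_components(gt, connectivity)
    pr_lab, pr_sizes = connected_components(pred, connectivity)
    g = np.asarray(gt_lab.data)
    p = np.asarray(pr_lab.data)
    n_gt_vox = int((g > 0).sum())
    n_pr_vox = int((p > 0).sum())
    inter = int(((g > 0) & (p > 0)).sum())
    if n_gt_vox + n_pr_vox == 0:
        dsc = 1.0  # two empty masks agree perfectly
    else:
        dsc = 2.0 * inter / (n_gt_vox + n_pr_vox)

    # overlap voxels per GT component / per pred component
    gt_overlap = np.bincount(g[(g > 0) & (p > 0)], minlength=len(gt_sizes) + 1)[1:]
    pr_overlap = np.bincount(p[(g > 0) & (p > 0)], minlength=len(pr_sizes) + 1)[1:]

    if min_overlap_frac > 0:
        detected = gt_overlap > min_overlap_frac * gt_sizes
    else:
        detected = gt_overlap > 0
    gt_df = pd.DataFrame({
        "id": np.arange(1, len(gt_sizes) + 1, dtype=int),
        "n_voxels": gt_sizes.astype(int),
        "overlap_voxels": gt_overlap.astype(int),
        "status": np.where(detected, "TP", "FN"),
    })
    pr_df = pd.DataFrame({
        "id": np.arange(1, len(pr_sizes) + 1, dtype=int),
        "n_voxels": pr_sizes.astype(int),
        "overlap_voxels": pr_overlap.astype(int),
        "status": np.where(pr_overlap > 0, "TP-associated", "FP"),
    })
    n_tp = int(detected.sum())
    n_fn = int(len(gt_sizes) - n_tp)
    n_fp = int((pr_overlap == 0).sum())

    if n_gt_vox > 0:
        scan_class = "TP" if n_pr_vox > 0 else "FN"
    else:
        scan_class = "FP" if n_pr_vox > 0 else "TN"
    return MatchResult(
        scan_id=scan_id,
        scan_class=scan_class,
        dsc=float(dsc),
        n_gt_voxels=n_gt_vox,
        n_pred_voxels=n_pr_vox,
        n_overlap_voxels=inter,
        gt_lesions=gt_df,
        pred_components=pr_df,
        n_tp=n_tp,
        n_fn=n_fn,
        n_fp=n_fp,
    )


def _median_range(values: list[float]) -> tuple[float, float, float] | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return float(np.median(arr)), float(arr.min()), float(arr.max())


@dataclass
class CohortSummary:
    """Pooled detection metrics across scans (the cohort-table quantities)."""

    n_scans: int
    scan_counts: dict  # scan-level TP/TN/FP/FN counts
    scan_sensitivity_pct: float | None
    scan_specificity_pct: float | None
    scan_accuracy_pct: float | None
    lesion_tp: int
    lesion_fn: int
    lesion_fp: int
    lesion_sensitivity_pct: float | None
    lesion_ppv_pct: float | None
    mean_scan_dsc: float | None    # mean per-scan DSC over scans with GT lesions
    pooled_voxel_dsc: float | None
    median_per_scan_sensitivity: tuple[float, float, float] | None  # (median, min, max)
    median_fp_per_scan: tuple[float, float, float] | None
    mean_fp_per_scan: float

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "TP": self.lesion_tp,
            "FN": self.lesion_fn,
            "FP": self.lesion_fp,
            "Sensitivity (%)": self.lesion_sensitivity_pct,
            "PPV (%)": self.lesion_ppv_pct,
            "Median per-scan sensitivity (%)": _fmt_mr(self.median_per_scan_sensitivity),
            "Median FP per scan": _fmt_mr(self.median_fp_per_scan),
            "DSC": self.mean_scan_dsc,
        }
        return pd.DataFrame({"metric": list(rows), "value": list(rows.values())})


def _fmt_mr(mr: tuple[float, float, float] | None) -> str | None:
    if mr is None:
        return None
    m, lo, hi = mr
    return f"{m:g} ({lo:g}, {hi:g})"


def summarize_cohort(results: list[MatchResult]) -> CohortSummary:
    """Pool per-scan match results into cohort detection metrics.

    Lesion-level sensitivity and PPV are pooled over all lesions
    (100*sum TP/(sum TP + sum FN), 100*sum TP/(sum TP + sum FP)); the cohort
    DSC is the mean of per-scan DSC over scans with a nonempty ground truth
    (pooled-voxel DSC is also reported); per-scan sensitivity medians
    exclude scans without GT lesions.
    """
    if not results:
        raise ParameterError("summarize_cohort needs at least one MatchResult")
    sc = {c: sum(r.scan_class == c for r in results) for c in ("TP", "TN", "FP", "FN")}
    sens = 100.0 * sc["TP"] / (sc["TP"] + sc["FN"]) if sc["TP"] + sc["FN"] else None
    spec = 100.0 * sc["TN"] / (sc["TN"] + sc["FP"]) if sc["TN"] + sc["FP"] else None
    acc = 100.0 * (sc["TP"] + sc["TN"]) / len(results)

    tp = sum(r.n_tp for r in results)
    fn = sum(r.n_fn for r in results)
    fp = sum(r.n_fp for r in results)
    l_sens = 100.0 * tp / (tp + fn) if tp + fn else None
    ppv = 100.0 * tp / (tp + fp) if tp + fp else None

    dscs = [r.dsc for r in results if r.n_gt_voxels > 0]
    tot_g = sum(r.n_gt_voxels for r in results)
    tot_p = sum(r.n_pred_voxels for r in results)
    tot_i = sum(r.n_overlap_voxels for r in results)
    pooled = 2.0 * tot_i / (tot_g + tot_p) if tot_g + tot_p else None

    per_scan_sens = [s for r in results if (s := r.per_scan_sensitivity) is not None]
    fp_counts = [float(r.n_fp) for r in results]
    return CohortSummary(
        n_scans=len(results),
        scan_counts=sc,
        scan_sensitivity_pct=sens,
        scan_specificity_pct=spec,
        scan_accuracy_pct=acc,
        lesion_tp=tp,
        lesion_fn=fn,
        lesion_fp=fp,
        lesion_sensitivity_pct=l_sens,
        lesion_ppv_pct=ppv,
        mean_scan_dsc=float(np.mean(dscs)) if dscs else None,
        pooled_voxel_dsc=pooled,
        median_per_scan_sensitivity=_median_range(per_scan_sens),
        median_fp_per_scan=_median_range(fp_counts),
        mean_fp_per_scan=float(np.mean(fp_counts)),
    )


def match_result_from_counts(
    n_tp: int, n_fn: int, n_fp: int, scan_id: str = "", scan_class: str = "TP"
) -> MatchResult:
    """Build a MatchResult carrying only lesion counts (no voxel data).

    Lets published confusion counts be pushed through the same cohort
    summary code as phantom runs.
    """
    gt_df = pd.DataFrame({
        "id": np.arange(1, n_tp + n_fn + 1),
        "n_voxels": 0,
        "overlap_voxels": 0,
        "status": ["TP"] * n_tp + ["FN"] * n_fn,
    })
    pr_df = pd.DataFrame({
        "id": np.arange(1, n_fp + 1),
        "n_voxels": 0,
        "overlap_voxels": 0,
        "status": ["FP"] * n_fp,
    })
    return MatchResult(
        scan_id=scan_id,
        scan_class=scan_class,
        dsc=float("nan"),
        n_gt_voxels=0,
        n_pred_voxels=0,
        n_overlap_voxels=0,
        gt_lesions=gt_df,
        pred_components=pr_df,
        n_tp=n_tp,
        n_fn=n_fn,
        n_fp=n_fp,
    )
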