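"""Threshold-based candidate annotation with programmatic accept/reject.

Emulates the semi-automated ground-truth workflow used clinically: a
global SUV threshold selects every voxel at or above the cutoff, spatially
distinct regions become candidate lesions, and an editing pass removes
physiologic-uptake candidates (e.g. spleen, kidney, bladder) and adds back
known low-uptake tumors supplied as explicit masks. The editing step is
rule-driven rather than interactive so the whole procedure is testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .grid import VolumeGrid
from .lesion_eval import connected_components
from .phantom import ORGAN_CODES


@dataclass
class CandidateSet:
    """Labeled threshold candidates over one PET volume."""

    labels: VolumeGrid          # integer labels 1..K
    records: pd.DataFrame       # id, n_voxels, suvmax, suvmean
    threshold: float
    connectivity: int = 26

    @property
    def ids(self) -> set[int]:
        return set(int(i) for i in self.records["id"])


def threshold_segment(
    pet: VolumeGrid, suv_threshold: float, connectivity: int = 26
) -> CandidateSet:
    """Segment every voxel with SUV >= threshold into distinct candidates.

    A region's SUVmax is at least the threshold iff it contains a voxel at
    or above it, so thresholding the voxel field realizes the "SUVmax >=
    t" candidate rule directly.
    """
    if not suv_threshold > 0:
        raise ParameterError(f"threshold must be positive, got {suv_threshold}")
    suv = np.asarray(pet.data, dtype=np.float64)
    binary = pet.like((suv >= suv_threshold).astype(np.int32))
    labels, sizes = connected_components(binary, connectivity)
    lab = np.asarray(labels.data)
    rows = []
    for k in range(1, len(sizes) + 1):
        vals = suv[lab == k]
        rows.append({
            "id": k,
            "n_voxels": int(sizes[k - 1]),
            "suvmax": float(vals.max()),
            "suvmean": float(vals.mean()),
        })
    records = pd.DataFrame(rows, columns=["id", "n_voxels", "suvmax", "suvmean"])
    return CandidateSet(labels=labels, records=records, threshold=float(suv_threshold),
                        connectivity=connectivity)


def edit_candidates(
    cands: CandidateSet,
    reject_ids: set[int] | list[int] = (),
    add_regions: list[VolumeGrid] = (),
) -> VolumeGrid:
    """Final binary mask = (non-rejected candidates) union (added regions)."""
    reject = {int(i) for i in reject_ids}
    unknown = reject - cands.ids
    if unknown:
        raise LookupError(f"unknown candidate ids: {sorted(unknown)}")
    lab = np.asarray(cands.labels.data)
    keep = (lab > 0) & ~np.isin(lab, sorted(reject))
    out = keep.copy()
    for region in add_regions:
        if not region.aligned_with(cands.labels):
            raise GeometryError("add region is not aligned with the candidate volume")
        out |= np.asarray(region.data) > 0
    return cands.labels.like(out.astype(np.int32))


def reject_by_organ_overlap(
    cands: CandidateSet,
    organ_labels: VolumeGrid,
    organs: list[str],
    min_frac: float = 0.5,
) -> set[int]:
    """Candidate ids with >= min_frac of their voxels inside given organs.

    The standard physiologic-uptake rejection rule: candidates mostly
    inside normal high-uptake organs are excluded from the ground truth.
    """
    if not cands.labels.aligned_with(organ_labels):
        raise GeometryError("organ labels not aligned with candidates")
    lab = np.asarray(cands.labels.data)
    org = np.asarray(organ_labels.data)
    codes = [ORGAN_CODES[o] for o in organs]
    inside = np.isin(org, codes)
    out: set[int] = set()
    for row in cands.records.itertuples(index=False):
        sel = lab == row.id
        if sel.sum() and inside[sel].mean() >= min_frac:
            out.add(int(row.id))
    return out
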