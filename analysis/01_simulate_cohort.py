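#!/usr/bin/env python
"""Generate the synthetic study cohort and summarize its composition.

Writes each scan's volumes (PET, CT, masks, organ labels) plus the lesion
truth tables under scratch/cohort/, and a per-scan composition table under
results/cohort_overview.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, cohort_config

from petleskit import degrade_mask, generate_scan
from petleskit.io import write_volume
from petleskit.pipeline import _scan_seed


def main() -> None:
    config = cohort_config()
    out = SCRATCH / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for i in range(config.n_scans):
        sid = f"scan{i:03d}"
        pid = f"patient{i // config.scans_per_patient:03d}"
        spec = config.phantom.with_(seed=_scan_seed(config.seed, i))
        scan = generate_scan(spec)
        deg = degrade_mask(scan.lesion_labels, scan.truth, config.degradation,
                           seed=_scan_seed(config.seed, 10_000 + i),
                           organ_labels=scan.organ_labels)
        d = out / sid
        write_volume(scan.pet, d / "pet.nii.gz")
        write_volume(scan.ct, d / "ct.nii.gz")
        write_volume(scan.gt_mask, d / "gt_mask.nii.gz")
        write_volume(deg.pred_mask, d / "pred_mask.nii.gz")
        write_volume(scan.organ_labels, d / "organ_labels.nii.gz")
        scan.truth.to_csv(d / "truth.csv", index=False)
        deg.flags.to_csv(d / "pred_flags.csv", index=False)
        rows.append({
            "scan_id": sid, "patient_id": pid,
            "n_lesions": len(scan.truth),
            "n_missed_by_degradation": int((~deg.flags.kept).sum()),
            "n_fp_blobs": deg.n_fp,
            "median_lesion_ttv_cm3": round(scan.truth.ttv_cm3.median(), 3),
            "median_lesion_peak_suv": round(scan.truth.peak_suv.median(), 2),
        })
    overview = pd.DataFrame(rows)
    overview.to_csv(RESULTS / "cohort_overview.csv", index=False)
    print(overview.to_string(index=False))
    print(f"\n{config.n_scans} scans, {overview.n_lesions.sum()} lesions total; "
          f"volumes under {out}")


if __name__ == "__main__":
    main()
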