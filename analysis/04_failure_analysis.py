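#!/usr/bin/env python
"""Where and why does the synthetic prediction fail?

Reads the per-lesion ledger from the detection run (analysis/02) and
writes (a) the region-by-status frequency table, (b) cluster-adjusted
Wilcoxon comparisons of SUVmax/TTV/TLU between TP, FN and FP lesions
(patients as clusters), and (c) liver tumor-to-background statistics,
under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from petleskit import clustered_wilcoxon, region_frequency


def main() -> None:
    ledger_path = RESULTS / "cohort_run" / "ledger.csv"
    if not ledger_path.exists():
        raise SystemExit("run analysis/02_detection_performance.py first")
    ledger = pd.read_csv(ledger_path)

    freq = region_frequency(ledger)
    freq.to_csv(RESULTS / "region_frequency.csv")
    print("Lesion frequency by anatomical region:")
    print(freq.to_string(), "\n")

    rows = []
    for col in ("suvmax", "ttv_cm3", "tlu"):
        for res in clustered_wilcoxon(ledger[col], ledger.status, ledger.cluster_id):
            rows.append({
                "parameter": col, "groups": f"{res.group_a} vs {res.group_b}",
                "z": round(res.statistic, 3), "p_value": res.p_value,
                "n_a": res.n_a, "n_b": res.n_b,
            })
    tests = pd.DataFrame(rows)
    tests.to_csv(RESULTS / "lesion_population_tests.csv", index=False)
    print("Cluster-adjusted rank-sum tests between lesion populations:")
    print(tests.to_string(index=False), "\n")

    liver = ledger[(ledger.region == "liver") & ledger.tbr.notna()]
    if len(liver):
        tbr = liver.groupby("status").tbr.agg(["count", "median"]).round(3)
        tbr.to_csv(RESULTS / "liver_tbr.csv")
        print("Liver tumor-to-background ratio by lesion status:")
        print(tbr.to_string(), "\n")

    fn = ledger[ledger.status == "FN"]
    tp = ledger[ledger.status == "TP"]
    print(
        f"Missed lesions are smaller and fainter than detected ones "
        f"(median SUVmax {fn.suvmax.median():.1f} vs {tp.suvmax.median():.1f}; "
        f"median TTV {fn.ttv_cm3.median():.2f} vs {tp.ttv_cm3.median():.2f} cm^3)."
    )


if __name__ == "__main__":
    main()
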