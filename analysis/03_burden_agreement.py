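#!/usr/bin/env python
"""Compare tumor burden (SUVmax, SUVmean, TTV, TLU) between predicted and
ground-truth masks across the cohort.

Reads per_scan.csv from the detection run (analysis/02) and writes the
agreement table - Bland-Altman mean difference with limits of agreement,
median relative mean difference, and ICC with interpretation band - under
results/burden_agreement.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from petleskit.pipeline import agreement_table


def main() -> None:
    per_scan_path = RESULTS / "cohort_run" / "per_scan.csv"
    if not per_scan_path.exists():
        raise SystemExit("run analysis/02_detection_performance.py first")
    per_scan = pd.read_csv(per_scan_path)
    table = agreement_table(per_scan)
    table.to_csv(RESULTS / "burden_agreement.csv", index=False)
    print(table.to_string(index=False))

    ttv = table.set_index("parameter").loc["ttv_cm3"]
    tlu = table.set_index("parameter").loc["tlu"]
    print(
        f"\nVolume-weighted burden is systematically underestimated by the "
        f"degraded predictions (TTV MD {ttv.md:.2f} cm^3, TLU MD {tlu.md:.2f}): "
        f"dropping lesions can only remove volume. SUVmax agrees closely "
        f"because the hottest lesions are rarely missed under the logistic "
        f"miss model."
    )


if __name__ == "__main__":
    main()
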