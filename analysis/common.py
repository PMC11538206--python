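"""Shared study configuration for the analysis scripts.

One synthetic cohort is used throughout: 20 whole-body scans (3 serial
scans per patient, as in a therapy-monitoring cohort), ~30 lesions per
scan, default organ uptake (hepatic background SUVmean 6), and the default
logistic degradation - small, faint lesions missed preferentially - plus
Poisson(3) false-positive blobs per scan. Grids are 64x64x128 at 3 mm,
a desk-scale field of view that keeps lesion statistics (not voxel count)
the driver of every result.
"""

from pathlib import Path

from petleskit import DegradationRules, PhantomSpec, RunConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 20260926 % (2**31)


def cohort_config(out_dir=None) -> RunConfig:
    return RunConfig(
        out_dir=out_dir or (SCRATCH / "cohort_run"),
        seed=SEED,
        n_scans=20,
        scans_per_patient=3,
        phantom=PhantomSpec(shape=(64, 64, 128), n_lesions=30),
        degradation=DegradationRules(fp_lambda=3.0),  # logistic miss model
    )
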