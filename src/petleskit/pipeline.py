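"""End-to-end orchestration: phantom cohort -> prediction -> evaluation ->
burden -> agreement -> failure analysis, with provenance.

A run is described by a :class:`RunConfig`. In phantom mode the pipeline
generates a cohort of synthetic scans (one root seed split per scan, so a
run is fully reproducible), degrades each ground truth into a synthetic
prediction, and pushes everything through the evaluation, burden,
agreement and failure stages. In manifest mode the same stages consume
NIfTI files listed in a pairing manifest (scan id, patient id, PET, GT
mask, predicted mask, optional organ label map).

Outputs: per-scan CSV, cohort detection tables (scan level and lesion
level), an agreement table (MD/limits, median RMD, ICC per burden
parameter), the per-lesion ledger, a region-by-status frequency table,
and a JSON run-metadata file containing the serialized config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import bland_altman, icc, median_rmd
from .burden import paired_burden
from .errors import InsufficientDataError, ParameterError, ReportError
from .failure import build_ledger, region_frequency
from .grid import VolumeGrid
from .io import read_volume
from .lesion_eval import MatchResult, connected_components, evaluate_scan, summarize_cohort
from .phantom import DegradationRules, PhantomSpec, degrade_mask, generate_scan

BURDEN_PARAMS = ("suvmax", "suvmean", "ttv_cm3", "tlu")


@dataclass
class RunConfig:
    """Declarative description of one end-to-end run."""

    out_dir: str | Path = "petleskit_run"
    seed: int = 0
    # phantom mode
    n_scans: int = 10
    scans_per_patient: int = 3  # cluster structure: serial scans per patient
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    degradation: DegradationRules = field(default_factory=DegradationRules)
    # manifest mode: CSV with scan_id, patient_id, pet, gt, pred[, organs]
    manifest: str | Path | None = None
    # evaluation parameters
    connectivity: int = 26
    min_overlap_frac: float = 0.0
    cluster_unit: str = "patient"  # or "scan"

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (Path, np.integer, np.floating)):
                return str(o) if isinstance(o, Path) else o.item()
            raise TypeError(f"not serializable: {o!r}")

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2, sort_keys=True)


@dataclass
class PipelineBundle:
    """In-memory result of a run plus the paths written."""

    config: RunConfig
    results: list[MatchResult]
    per_scan: pd.DataFrame
    cohort_detection: pd.DataFrame
    scan_level: pd.DataFrame
    agreement: pd.DataFrame
    ledger: pd.DataFrame
    region_freq: pd.DataFrame | None
    out_dir: Path | None


def _scan_seed(root: int, i: int) -> int:
    return int(np.random.SeedSequence([root, i]).generate_state(1)[0] % (2**31))


def _iter_phantom(config: RunConfig):
    for i in range(config.n_scans):
        sid = f"scan{i:03d}"
        pid = f"patient{i // max(config.scans_per_patient, 1):03d}"
        spec = config.phantom.with_(seed=_scan_seed(config.seed, i))
        scan = generate_scan(spec)
        deg = degrade_mask(
            scan.lesion_labels, scan.truth, config.degradation,
            seed=_scan_seed(config.seed, 10_000 + i),
            organ_labels=scan.organ_labels,
        )
        yield sid, pid, scan.pet, scan.gt_mask, deg.pred_mask, scan.organ_labels


def _iter_manifest(config: RunConfig):
    man = pd.read_csv(config.manifest)
    required = {"scan_id", "patient_id", "pet", "gt", "pred"}
    missing = required - set(man.columns)
    if missing:
        raise ParameterError(f"manifest missing columns: {sorted(missing)}")
    for row in man.itertuples(index=False):
        pet = read_volume(row.pet, "pet")
        gt = read_volume(row.gt, "mask")
        pred = read_volume(row.pred, "mask")
        organs = None
        if "organs" in man.columns and isinstance(row.organs, str) and row.organs:
            organs = read_volume(row.organs, "labels")
        yield str(row.scan_id), str(row.patient_id), pet, gt, pred, organs


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineBundle:
    """Execute all stages; deterministic given the config seed."""
    scans = _iter_manifest(config) if config.manifest else _iter_phantom(config)

    results: list[MatchResult] = []
    per_scan_rows = []
    ledger_parts = []
    for sid, pid, pet, gt, pred, organs in scans:
        res = evaluate_scan(gt, pred, scan_id=sid, connectivity=config.connectivity,
                            min_overlap_frac=config.min_overlap_frac)
        gt_rep, pr_rep = paired_burden(pet, gt, pred, config.connectivity)
        gt_lab, _ = connected_components(gt, config.connectivity)
        pr_lab, _ = connected_components(pred, config.connectivity)
        cluster = pid if config.cluster_unit == "patient" else sid
        ledger_parts.append(build_ledger(
            sid, cluster, pet, gt_lab, pr_lab,
            res.gt_lesions, res.pred_components, organs,
        ))
        results.append(res)
        per_scan_rows.append({
            "scan_id": sid, "patient_id": pid, "scan_class": res.scan_class,
            "dsc": res.dsc, "n_tp": res.n_tp, "n_fn": res.n_fn, "n_fp": res.n_fp,
            "per_scan_sensitivity_pct": res.per_scan_sensitivity,
            "gt_suvmax": gt_rep.suvmax, "pred_suvmax": pr_rep.suvmax,
            "gt_suvmean": gt_rep.suvmean, "pred_suvmean": pr_rep.suvmean,
            "gt_ttv_cm3": gt_rep.ttv_cm3, "pred_ttv_cm3": pr_rep.ttv_cm3,
            "gt_tlu": gt_rep.tlu, "pred_tlu": pr_rep.tlu,
        })
    if not results:
        raise ParameterError("pipeline produced no scans")
    per_scan = pd.DataFrame(per_scan_rows)
    ledger = pd.concat(ledger_parts, ignore_index=True) if ledger_parts else pd.DataFrame()

    summary = summarize_cohort(results)
    cohort_detection = summary.to_frame()
    scan_level = pd.DataFrame({
        "metric": ["TP", "FN", "FP", "TN", "Sensitivity (%)", "Accuracy (%)", "Dice"],
        "value": [
            summary.scan_counts["TP"], summary.scan_counts["FN"],
            summary.scan_counts["FP"], summary.scan_counts["TN"],
            summary.scan_sensitivity_pct, summary.scan_accuracy_pct,
            summary.mean_scan_dsc,
        ],
    })
    agreement = agreement_table(per_scan)
    region_freq = region_frequency(ledger) if not ledger.empty else None

    out_dir = None
    if write:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_scan.to_csv(out_dir / "per_scan.csv", index=False)
        cohort_detection.to_csv(out_dir / "cohort_detection.csv", index=False)
        scan_level.to_csv(out_dir / "scan_level.csv", index=False)
        agreement.to_csv(out_dir / "agreement.csv", index=False)
        ledger.to_csv(out_dir / "ledger.csv", index=False)
        if region_freq is not None:
            region_freq.to_csv(out_dir / "region_frequency.csv")
        (out_dir / "run_metadata.json").write_text(json.dumps({
            "config": json.loads(config.to_json()),
            "n_scans": len(results),
        }, indent=2, sort_keys=True))
    return PipelineBundle(
        config=config, results=results, per_scan=per_scan,
        cohort_detection=cohort_detection, scan_level=scan_level,
        agreement=agreement, ledger=ledger, region_freq=region_freq,
        out_dir=out_dir,
    )


def agreement_table(per_scan: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter agreement (MD, limits, median RMD, ICC) from the
    paired per-scan burden columns. Parameters with too few valid pairs
    are reported with NaNs rather than failing the run."""
    rows = []
    for p in BURDEN_PARAMS:
        ai = per_scan[f"pred_{p}"].to_numpy(dtype=float)
        gt = per_scan[f"gt_{p}"].to_numpy(dtype=float)
        row = {"parameter": p}
        try:
            ba = bland_altman(ai, gt)
            row.update(md=ba.md, loa_low=ba.loa_low, loa_high=ba.loa_high,
                       n_outliers=len(ba.outliers))
        except InsufficientDataError:
            row.update(md=np.nan, loa_low=np.nan, loa_high=np.nan, n_outliers=np.nan)
        try:
            med, lo, hi, n_excl = median_rmd(ai, gt)
            row.update(median_rmd=med, rmd_min=lo, rmd_max=hi, rmd_excluded=n_excl)
        except InsufficientDataError:
            row.update(median_rmd=np.nan, rmd_min=np.nan, rmd_max=np.nan, rmd_excluded=np.nan)
        try:
            ic = icc(ai, gt)
            row.update(icc=ic.value, icc_category=ic.category,
                       icc_consistency=ic.value_consistency)
        except InsufficientDataError:
            row.update(icc=np.nan, icc_category="undefined", icc_consistency=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _md_table(df: pd.DataFrame, title: str, float_fmt: str = "{:.4g}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return "" if np.isnan(v) else float_fmt.format(v)
        return "" if v is None else str(v)

    cols = list(df.columns)
    lines = [f"### {title}", "", "| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, r in df.iterrows():
        lines.append("| " + " | ".join(fmt(r[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def render_report(bundle: PipelineBundle) -> str:
    """Markdown report with scan-level, lesion-level and agreement tables."""
    for name in ("scan_level", "cohort_detection", "agreement"):
        if getattr(bundle, name) is None:
            raise ReportError(f"bundle is missing {name}")
    if bundle.cohort_detection.empty:
        raise ReportError("empty cohort")
    parts = [
        _md_table(bundle.scan_level, "Scan-level performance"),
        _md_table(bundle.cohort_detection, "Lesion-level performance"),
        _md_table(bundle.agreement, "Tumor-burden agreement (AI vs GT)"),
    ]
    if bundle.region_freq is not None:
        parts.append(_md_table(bundle.region_freq.reset_index(),
                               "Lesion frequency by anatomical region"))
    return "\n".join(parts)
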