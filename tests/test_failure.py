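"""Region assignment, frequency tables, and liver tumor-to-background ratios."""

import numpy as np
import pandas as pd
import pytest

from petleskit import (
    DegradationRules,
    PhantomSpec,
    VolumeGrid,
    assign_regions,
    connected_components,
    degrade_mask,
    evaluate_scan,
    generate_scan,
    liver_tbr,
    region_frequency,
)
from petleskit.errors import ParameterError
from petleskit.failure import build_ledger, tbr_for_lesions
from petleskit.phantom import ORGAN_CODES, LesionSpec


def _labels(arr):
    return VolumeGrid(np.asarray(arr, dtype=np.int32), spacing=(1, 1, 1))


def test_full_containment():
    organs = np.zeros((6, 6, 6), dtype=int)
    organs[2:5, 2:5, 2:5] = ORGAN_CODES["liver"]
    lesions = np.zeros((6, 6, 6), dtype=int)
    lesions[3, 3, 3] = 1
    assert assign_regions(_labels(lesions), _labels(organs)) == {1: "liver"}


def test_plurality_rule_and_background_unassigned():
    organs = np.zeros((10, 1, 1), dtype=int)
    organs[:3, 0, 0] = ORGAN_CODES["liver"]
    lesions = np.zeros((10, 1, 1), dtype=int)
    lesions[:5, 0, 0] = 1   # 3 liver, 2 background -> liver
    lesions[5:10, 0, 0] = 2  # all background -> unassigned
    out = assign_regions(_labels(lesions), _labels(organs))
    assert out == {1: "liver", 2: "unassigned"}


def test_tie_breaks_to_smaller_code():
    organs = np.zeros((4, 1, 1), dtype=int)
    organs[0:2, 0, 0] = ORGAN_CODES["liver"]   # code 4
    organs[2:4, 0, 0] = ORGAN_CODES["spleen"]  # code 5
    lesions = np.zeros((4, 1, 1), dtype=int)
    lesions[:, 0, 0] = 1  # 2 vs 2 tie
    assert assign_regions(_labels(lesions), _labels(organs)) == {1: "liver"}


def test_phantom_regions_match_truth_tags(small_scan):
    regions = assign_regions(small_scan.lesion_labels, small_scan.organ_labels)
    truth_map = dict(zip(small_scan.truth.lesion_id, small_scan.truth.region))
    matches = sum(regions[k] == truth_map[k] for k in truth_map)
    # truth tags use the center voxel; plurality can differ near boundaries
    assert matches >= 0.75 * len(truth_map)


def test_region_frequency_counts_and_margins():
    ledger = pd.DataFrame({
        "region": ["liver"] * 4 + ["lung"],
        "status": ["FN", "FN", "FN", "TP", "FP"],
    })
    tab = region_frequency(ledger)
    assert tab.loc["liver", "TP"] == 1
    assert tab.loc["liver", "FN"] == 3
    assert tab.loc["liver", "FP"] == 0
    assert tab.values.sum() == len(ledger)


def test_region_frequency_empty_rejected():
    with pytest.raises(ParameterError):
        region_frequency(pd.DataFrame())


def test_tbr_simple_ratios():
    assert tbr_for_lesions([12.0], 6.0)[0] == pytest.approx(2.0)
    assert tbr_for_lesions([6.0], 6.0)[0] == pytest.approx(1.0)


def test_liver_suvmean_excludes_lesion_voxels():
    organs = np.zeros((4, 4, 4), dtype=int)
    organs[:, :, :2] = ORGAN_CODES["liver"]
    pet = np.full((4, 4, 4), 6.0)
    lesions = np.zeros((4, 4, 4), dtype=int)
    lesions[0, 0, 0] = 1
    pet[0, 0, 0] = 40.0  # hot lesion inside the liver
    mean, n = liver_tbr(
        VolumeGrid(pet, (1, 1, 1)), _labels(lesions), _labels(organs)
    )
    assert mean == pytest.approx(6.0)
    assert n == 31


def test_tbr_undefined_without_liver_label():
    organs = np.zeros((3, 3, 3), dtype=int)
    with pytest.raises(ParameterError):
        liver_tbr(
            VolumeGrid(np.ones((3, 3, 3)), (1, 1, 1)),
            _labels(np.zeros((3, 3, 3))),
            _labels(organs),
        )


def test_ledger_covers_every_lesion_once(small_scan):
    deg = degrade_mask(small_scan.lesion_labels, small_scan.truth,
                       DegradationRules(miss_prob=0.4, fp_lambda=3.0), seed=8,
                       organ_labels=small_scan.organ_labels)
    res = evaluate_scan(small_scan.gt_mask, deg.pred_mask)
    gt_lab, _ = connected_components(small_scan.gt_mask)
    pr_lab, _ = connected_components(deg.pred_mask)
    ledger = build_ledger("s0", "p0", small_scan.pet, gt_lab, pr_lab,
                          res.gt_lesions, res.pred_components, small_scan.organ_labels)
    assert len(ledger) == res.n_tp + res.n_fn + res.n_fp
    assert ledger.lesion_uid.is_unique
    counts = ledger.status.value_counts()
    assert counts.get("TP", 0) == res.n_tp
    assert counts.get("FN", 0) == res.n_fn
    assert counts.get("FP", 0) == res.n_fp


def test_liver_targeted_fp_concentrate_in_liver_row(small_scan):
    deg = degrade_mask(small_scan.lesion_labels, small_scan.truth,
                       DegradationRules(miss_prob=0.0, fp_lambda=6.0, fp_region="liver"),
                       seed=5, organ_labels=small_scan.organ_labels)
    assert deg.n_fp > 0
    res = evaluate_scan(small_scan.gt_mask, deg.pred_mask)
    gt_lab, _ = connected_components(small_scan.gt_mask)
    pr_lab, _ = connected_components(deg.pred_mask)
    ledger = build_ledger("s0", "p0", small_scan.pet, gt_lab, pr_lab,
                          res.gt_lesions, res.pred_components, small_scan.organ_labels)
    tab = region_frequency(ledger)
    assert tab["FP"].sum() == tab.loc["liver", "FP"]


def test_fn_liver_lesions_have_lower_tbr_than_tp():
    """Low-contrast liver lesions (TBR ~ 1.2) dropped, hot ones kept: the FN
    population's median TBR sits below the TP population's and the
    cluster-adjusted test calls the difference significant."""
    from petleskit import cluster_ranksum

    tbr_tp, tbr_fn, cl_tp, cl_fn = [], [], [], []
    for s in range(8):
        # two columns of small spheres inside the liver: hot (kept) and faint
        lesions = (
            [LesionSpec((26, 20, 36 + 4 * j), 4.5, 24.0) for j in range(4)]
            + [LesionSpec((33, 24, 36 + 4 * j), 4.5, 7.5) for j in range(4)]
        )
        spec = PhantomSpec(shape=(48, 48, 96), lesions=lesions, seed=40 + s)
        scan = generate_scan(spec)
        # drop exactly the low-uptake lesions (ids 5..8)
        lab = np.asarray(scan.lesion_labels.data)
        pred = scan.gt_mask.like(((lab >= 1) & (lab <= 4)).astype(np.int32))
        res = evaluate_scan(scan.gt_mask, pred)
        gt_lab, _ = connected_components(scan.gt_mask)
        pr_lab, _ = connected_components(pred)
        ledger = build_ledger(f"s{s}", f"p{s}", scan.pet, gt_lab, pr_lab,
                              res.gt_lesions, res.pred_components, scan.organ_labels)
        liver_rows = ledger[ledger.region == "liver"]
        tbr_tp.extend(liver_rows[liver_rows.status == "TP"].tbr.dropna())
        cl_tp.extend([s] * (liver_rows.status == "TP").sum())
        tbr_fn.extend(liver_rows[liver_rows.status == "FN"].tbr.dropna())
        cl_fn.extend([s] * (liver_rows.status == "FN").sum())
    assert np.median(tbr_fn) < np.median(tbr_tp)
    res = cluster_ranksum(tbr_fn, tbr_tp, cl_fn, cl_tp)
    assert res.p_value < 0.05
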